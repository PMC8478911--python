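"""Whole-community analysis of benthic cover.

Site-year mean covers are square-root transformed into a community
matrix, visualized with non-metric multidimensional scaling (NMDS, on
Bray-Curtis dissimilarities by default), and tested with redundancy
analysis (RDA): sequential multivariate least squares on the metadata
terms, variance of the fitted values per term, and a permutation ANOVA
(unrestricted row permutation, pseudo-F) for significance.

The RDA and its permutation test are implemented natively (projection +
eigen-decomposition + permutation loop); NMDS optimization delegates to
scikit-learn's SMACOF-based non-metric MDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS


@dataclass
class CommunityMatrix:
    """Rows = site-year units, columns = benthic groups, entries =
    sqrt(mean cover); row metadata (site, year, reef_type) travels
    alongside.  Rows are kept in canonical (site, year) order so seeded
    analyses are invariant to input row order."""

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("sqrt-cover entries must lie in [0, 1]")
        if len(self.meta) != len(self.values):
            raise ValueError("metadata must have one row per unit")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_matrix(cover: pd.DataFrame) -> CommunityMatrix:
    """Build the sqrt-transformed site-year x group matrix from an
    aggregated cover table (one mean-cover row per site-year-label;
    absent groups become 0)."""
    req = {"site", "year", "label", "cover"}
    missing = req - set(cover.columns)
    if missing:
        raise ValueError(f"cover table missing columns: {sorted(missing)}")
    dup = cover.duplicated(subset=["site", "year", "label"])
    if dup.any():
        raise ValueError("duplicate site-year-label rows in cover table")
    wide = cover.pivot_table(
        index=["site", "year"], columns="label", values="cover", fill_value=0.0
    ).sort_index()
    values = np.sqrt(wide)
    meta = wide.index.to_frame(index=False)
    if "reef_type" in cover.columns:
        rt = cover.drop_duplicates(["site", "year"])[["site", "year", "reef_type"]]
        meta = meta.merge(rt, on=["site", "year"], how="left")
    return CommunityMatrix(values=values.reset_index(drop=True), meta=meta)


# ------------------------------------------------------------------- NMDS


@dataclass
class NMDSResult:
    coords: pd.DataFrame
    stress: float
    interpretation: str = ""


def interpret_stress(stress: float) -> str:
    """Conventional reading of Kruskal stress-1 for an ordination."""
    if stress < 0.1:
        return "excellent (< 0.1)"
    if stress <= 0.2:
        return "good to excellent (0.1-0.2)"
    return "poor (> 0.2)"


class NMDSOrdination(BaseEstimator):
    """Non-metric MDS of a community matrix.

    Monotone-regression stress is minimized over ``n_init`` seeded random
    restarts; ``stress_`` is Kruskal stress-1.
    """

    def __init__(
        self,
        n_components: int = 2,
        metric: str = "braycurtis",
        n_init: int = 20,
        max_iter: int = 300,
        eps: float = 1e-6,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.metric = metric
        self.n_init = n_init
        self.max_iter = max_iter
        self.eps = eps
        self.seed = seed

    def fit_transform(self, m: CommunityMatrix, y=None) -> np.ndarray:
        vals = m.values.to_numpy(dtype=float)
        if len(vals) < self.n_components + 2:
            raise ValueError("need at least k + 2 rows for a k-dimensional NMDS")
        if np.allclose(vals, vals[0]):
            raise ValueError("all rows identical; ordination degenerate")
        diss = squareform(pdist(vals, metric=self.metric))
        mds = MDS(
            n_components=self.n_components,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=self.n_init,
            max_iter=self.max_iter,
            eps=self.eps,
            random_state=self.seed,
            normalized_stress=True,
        )
        coords = mds.fit_transform(diss)
        self.stress_ = float(mds.stress_)
        self.embedding_ = coords
        return coords

    def fit(self, m: CommunityMatrix, y=None) -> "NMDSOrdination":
        self.fit_transform(m)
        return self


def run_nmds(m: CommunityMatrix, k: int = 2, seed: int = 0, **kwargs) -> NMDSResult:
    """Functional wrapper over :class:`NMDSOrdination`."""
    est = NMDSOrdination(n_components=k, seed=seed, **kwargs)
    coords = est.fit_transform(m)
    df = m.meta.copy()
    for j in range(k):
        df[f"nmds{j + 1}"] = coords[:, j]
    return NMDSResult(
        coords=df, stress=est.stress_, interpretation=interpret_stress(est.stress_)
    )


# -------------------------------------------------------------------- RDA


@dataclass
class OrdinationResult:
    """RDA permutation-ANOVA output: per-term table (df, variance
    fraction, pseudo-F, permutation p), axis eigenvalues, permutation
    count."""

    anova: pd.DataFrame
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    n_perm: int
    total_variance: float
    residual_variance: float

    def p_value(self, term: str) -> float:
        hit = self.anova.loc[self.anova["term"] == term, "p_value"]
        if hit.empty:
            raise KeyError(f"no term {term!r}")
        return float(hit.iloc[0])


def _dummy(values: pd.Series, as_factor: bool) -> np.ndarray:
    if as_factor:
        return pd.get_dummies(values.astype("category")).to_numpy(dtype=float)
    return values.to_numpy(dtype=float)[:, None]


class RDAPermutationANOVA(BaseEstimator):
    """Redundancy analysis with a sequential permutation ANOVA.

    Terms are added in order; each term's statistic is the pseudo-F of
    the variance it adds over the previous terms against the full-model
    residual.  Significance comes from ``n_perm`` unrestricted row
    permutations of the (centered) response, p = (1 + #{F* >= F}) /
    (1 + n_perm).  Year is treated as a categorical term by default.
    """

    def __init__(
        self,
        terms: tuple[str, ...] = ("reef_type", "locality", "year"),
        n_perm: int = 999,
        year_as_factor: bool = True,
        seed: int = 0,
    ):
        self.terms = terms
        self.n_perm = n_perm
        self.year_as_factor = year_as_factor
        self.seed = seed

    def fit(self, m: CommunityMatrix, y=None) -> "RDAPermutationANOVA":
        meta = m.meta.rename(columns={"site": "locality"})
        Y = m.values.to_numpy(dtype=float)
        n = Y.shape[0]
        Y = Y - Y.mean(axis=0)
        ss_total = float((Y**2).sum())

        # sequential orthonormal design blocks
        basis = np.ones((n, 1)) / np.sqrt(n)
        blocks: list[tuple[str, np.ndarray]] = []
        for term in self.terms:
            if term not in meta.columns:
                raise ValueError(f"metadata has no column for term {term!r}")
            X = _dummy(meta[term], term != "year" or self.year_as_factor)
            resid = X - basis @ (basis.T @ X)
            q, r = np.linalg.qr(resid)
            keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
            q = q[:, keep]
            if q.shape[1] == 0:
                raise ValueError(
                    f"term {term!r} is aliased with earlier terms "
                    f"({', '.join(t for t, _ in blocks)})"
                )
            blocks.append((term, q))
            basis = np.hstack([basis, q])

        Q = np.hstack([q for _, q in blocks])
        dfs = np.array([q.shape[1] for _, q in blocks])
        edges = np.concatenate([[0], np.cumsum(dfs)])
        df_res = n - 1 - int(dfs.sum())
        if df_res <= 0:
            raise ValueError("saturated design; no residual degrees of freedom")

        def stats_for(Yp: np.ndarray) -> tuple[np.ndarray, float]:
            G = Q.T @ Yp
            per_col = (G**2).sum(axis=1)
            ss_terms = np.array(
                [per_col[edges[i] : edges[i + 1]].sum() for i in range(len(blocks))]
            )
            ss_res = float((Yp**2).sum()) - float(ss_terms.sum())
            F = (ss_terms / dfs) / (ss_res / df_res)
            return ss_terms, F  # type: ignore[return-value]

        ss_obs, F_obs = stats_for(Y)
        rng = np.random.default_rng(self.seed)
        exceed = np.zeros(len(blocks))
        for _ in range(self.n_perm):
            perm = rng.permutation(n)
            _, F_p = stats_for(Y[perm])
            exceed += F_p >= F_obs
        p = (1.0 + exceed) / (1.0 + self.n_perm)

        fitted = Q @ (Q.T @ Y)
        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        eig = (s**2) / (n - 1)
        anova = pd.DataFrame(
            {
                "term": [t for t, _ in blocks],
                "df": dfs,
                "variance": ss_obs / (n - 1),
                "variance_fraction": ss_obs / ss_total,
                "F": F_obs,
                "p_value": p,
            }
        )
        self.result_ = OrdinationResult(
            anova=anova,
            eigenvalues=eig[eig > 1e-12],
            site_scores=u * s,
            n_perm=self.n_perm,
            total_variance=ss_total / (n - 1),
            residual_variance=(ss_total - float(ss_obs.sum())) / (n - 1),
        )
        return self


def rda_perm_anova(
    m: CommunityMatrix,
    terms: tuple[str, ...] = ("reef_type", "locality", "year"),
    n_perm: int = 999,
    seed: int = 0,
    **kwargs,
) -> OrdinationResult:
    """Functional wrapper over :class:`RDAPermutationANOVA`."""
    est = RDAPermutationANOVA(terms=terms, n_perm=n_perm, seed=seed, **kwargs)
    return est.fit(m).result_
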