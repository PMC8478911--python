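"""Temporal trend models for proportional benthic cover.

Cover fractions live on [0, 1] but a beta likelihood requires (0, 1), so
observed proportions are first squeezed off the boundary with

    p* = (p (n - 1) + 0.5) / n,

where n is the number of observations entering the model.  Trends are
then fit with a generalized additive model under a beta family with logit
link: a parametric reef-type effect, a global smooth of year, a deviation
smooth of year for each non-reference reef type, and a random-intercept
smooth for locality.  The deviation (ordered-factor) parameterization
keeps the year smooths identifiable — with one smooth per reef type plus
a global smooth, the linear parts of the smooths are confounded and
term-wise tests lose their meaning — while still answering the questions
the per-type structure poses: the global smooth is the reference
(patch-reef) trend and each deviation smooth tests whether that reef type
departs from it.

With only a handful of distinct survey years the year smooths default to
fixed-df regression splines (k - 1 df each) rather than penalized ones:
penalization has almost no room to act on so few covariate values, and
fixed-df smooths give Wald chi-square term tests with known degrees of
freedom, which simulation shows to be accurately sized where tests
conditional on estimated smoothing parameters run noticeably liberal.
``penalized=True`` restores REML-penalized year smooths.  The locality
random intercept is always a penalized ("re") term.

GAM numerics are delegated to mgcv (invoked through ``Rscript``), the
standard engine for beta-family additive models; model assembly, the
boundary transform, batch simulation support and all calibration checks
are this module's own.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sites import FIXED_TRANSECT_SITES


class TrendConvergenceError(Exception):
    """The GAM engine failed to converge; carries engine diagnostics."""


def squeeze_transform(p, n: int):
    """Shift proportions off {0, 1}: ``(p (n - 1) + 0.5) / n``.

    Strictly inside (0, 1) for any p in [0, 1] and n >= 2; monotone in p;
    fixed point at p = 0.5.  Accepts scalars or arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if int(n) < 2 or int(n) != n:
        raise ValueError("n must be an integer >= 2")
    out = (p_arr * (n - 1) + 0.5) / n
    return float(out) if np.isscalar(p) else out


@dataclass(frozen=True)
class TrendModelSpec:
    """Structure of the cover trend model."""

    response: str = "cover"
    k: int = 5  # year-smooth basis dimension; years are few, so small
    include_reef_type: bool = True
    include_random_effect: bool = True
    penalized: bool = False


@dataclass
class TrendFit:
    """Fitted summaries: per-term tests (z for parametric terms,
    chi-square for smooths), deviance explained, and back-transformed
    fitted year curves with 95% intervals per reef type."""

    term_table: pd.DataFrame
    deviance_explained: float
    curves: pd.DataFrame
    n_obs: int
    phi: float
    diagnostics: dict = field(default_factory=dict)
    dropped_random_effect: bool = False

    def p_value(self, term: str) -> float:
        hit = self.term_table.loc[self.term_table["term"] == term, "p_value"]
        if hit.empty:
            raise KeyError(
                f"no term {term!r}; have {list(self.term_table['term'])}"
            )
        return float(hit.iloc[0])


_TERM_RENAMES = {
    "s(site)": "s(locality)",
}


def _nice_term(raw: str) -> str:
    if raw in _TERM_RENAMES:
        return _TERM_RENAMES[raw]
    if raw.startswith("reef_type") and raw != "reef_type":
        return f"reef_type[{raw[len('reef_type'):]}]"
    if raw.startswith("s(year):reef_o"):
        return f"s(year):{raw[len('s(year):reef_o'):]}"
    return raw


def _engine_script() -> Path:
    return Path(resources.files("reefquad") / "trend_gam.R")


def _run_engine(
    frames: list[pd.DataFrame], k: int, n_curve: int, penalized: bool = False
) -> list[dict]:
    stacked = pd.concat(
        [f.assign(dataset=i) for i, f in enumerate(frames)], ignore_index=True
    )
    with tempfile.TemporaryDirectory() as td:
        in_csv = Path(td) / "data.csv"
        out_json = Path(td) / "fits.json"
        stacked.to_csv(in_csv, index=False)
        cmd = [
            "Rscript",
            "--vanilla",
            str(_engine_script()),
            str(in_csv),
            str(out_json),
            str(k),
            str(n_curve),
            "1" if penalized else "0",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not out_json.exists():
            raise RuntimeError(
                "GAM engine (Rscript/mgcv) failed:\n" + proc.stderr[-2000:]
            )
        results = json.loads(out_json.read_text())
    by_ds = {r["dataset"]: r for r in results}
    return [by_ds[i] for i in range(len(frames))]


def _prepare(data: pd.DataFrame, spec: TrendModelSpec) -> pd.DataFrame:
    req = {"site", "year", spec.response}
    missing = req - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")
    d = data.copy()
    if d["year"].nunique() < 2:
        raise ValueError("need at least 2 distinct years")
    n = len(d)
    d["y"] = squeeze_transform(d[spec.response].to_numpy(), n)
    cols = ["site", "year", "y"]
    if spec.include_reef_type and "reef_type" in d.columns:
        if d["reef_type"].nunique() > 1:
            cols.append("reef_type")
    return d[cols]


def _to_fit(res: dict) -> TrendFit:
    if not res.get("converged", False):
        raise TrendConvergenceError(
            f"beta-GAM did not converge: {res.get('error', 'no details')}"
        )
    terms = pd.DataFrame(res["terms"])
    terms["term"] = terms["term"].map(_nice_term)
    curves = pd.DataFrame(res["curves"])
    return TrendFit(
        term_table=terms[["term", "type", "statistic", "p_value"]],
        deviance_explained=float(res["deviance_explained"]),
        curves=curves,
        n_obs=int(res["n_obs"]),
        phi=float(res["phi"]),
        diagnostics=res.get("diagnostics", {}),
        dropped_random_effect=bool(res.get("dropped_random_effect", False)),
    )


class BetaTrendGAM(BaseEstimator):
    """Estimator interface to the beta-GAM trend model.

    ``fit`` takes a tidy frame with columns site, year, cover (and
    optionally reef_type); fitted summaries land in ``term_table_``,
    ``deviance_explained_``, ``curves_`` and ``diagnostics_``.
    """

    def __init__(
        self,
        response: str = "cover",
        k: int = 5,
        include_reef_type: bool = True,
        penalized: bool = False,
        n_curve: int = 25,
    ):
        self.response = response
        self.k = k
        self.include_reef_type = include_reef_type
        self.penalized = penalized
        self.n_curve = n_curve

    def _spec(self) -> TrendModelSpec:
        return TrendModelSpec(
            response=self.response,
            k=self.k,
            include_reef_type=self.include_reef_type,
            penalized=self.penalized,
        )

    def fit(self, data: pd.DataFrame, y=None) -> "BetaTrendGAM":
        prepared = _prepare(data, self._spec())
        res = _run_engine([prepared], self.k, self.n_curve, self.penalized)[0]
        fit = _to_fit(res)
        self.fit_ = fit
        self.term_table_ = fit.term_table
        self.deviance_explained_ = fit.deviance_explained
        self.curves_ = fit.curves
        self.diagnostics_ = fit.diagnostics
        self.n_obs_ = fit.n_obs
        return self

    def predict(self, year=None, reef_type=None) -> pd.DataFrame:
        """Fitted mean-cover curve (with 95% interval), optionally
        filtered to given years/reef type."""
        if not hasattr(self, "curves_"):
            raise RuntimeError("call fit first")
        out = self.curves_
        if reef_type is not None:
            out = out[out["reef_type"] == reef_type]
        if year is not None:
            out = out[np.isin(out["year"], np.atleast_1d(year))]
        return out.reset_index(drop=True)


def fit_trend_gam(
    data: pd.DataFrame,
    response: str = "cover",
    k: int = 5,
    include_reef_type: bool = True,
    penalized: bool = False,
) -> TrendFit:
    """Fit the cover trend beta-GAM; see :class:`BetaTrendGAM`."""
    est = BetaTrendGAM(
        response=response, k=k, include_reef_type=include_reef_type,
        penalized=penalized,
    )
    return est.fit(data).fit_


def fit_trend_gam_batch(
    datasets: list[pd.DataFrame],
    response: str = "cover",
    k: int = 5,
    include_reef_type: bool = True,
    penalized: bool = False,
    n_curve: int = 2,
) -> list[TrendFit | None]:
    """Fit many datasets in one engine invocation (simulation studies).

    Returns one :class:`TrendFit` per dataset, ``None`` where the engine
    failed to converge.
    """
    spec = TrendModelSpec(
        response=response, k=k, include_reef_type=include_reef_type,
        penalized=penalized,
    )
    prepared = [_prepare(d, spec) for d in datasets]
    results = _run_engine(prepared, k, n_curve, penalized)
    fits: list[TrendFit | None] = []
    for res in results:
        try:
            fits.append(_to_fit(res))
        except TrendConvergenceError:
            fits.append(None)
    return fits


def fixed_transect_sensitivity(
    data: pd.DataFrame, response: str = "cover", k: int = 5
) -> TrendFit:
    """Re-fit the trend model on fixed-transect sites only.

    Rows are filtered by a ``transect_type`` column when present,
    otherwise by the default fixed-transect site roster.  Reef-type terms
    drop out (a single reef type remains by design).
    """
    if "transect_type" in data.columns:
        sub = data[data["transect_type"] == "fixed"]
    else:
        sub = data[data["site"].isin(FIXED_TRANSECT_SITES)]
    if sub.empty:
        raise ValueError("no fixed-transect rows to fit")
    return fit_trend_gam(sub, response=response, k=k, include_reef_type=False)
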