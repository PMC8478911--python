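"""Label schema for point annotation of benthic imagery.

The default schema follows the CATAMI-style functional groups used for
shallow Caribbean reef monitoring (macroalgae, long turfing algae,
scleractinian corals, octocorals, sponges, sand, rubble, plus a
"consolidated substrate" class for the epilithic algal matrix), together
with image-quality labels (shadow, transect tape, unidentifiable) that are
excluded from cover denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

BENTHIC = "benthic"
QUALITY = "quality"

DEFAULT_LABELS: list[tuple[str, str, str]] = [
    ("MA", "macroalgae", BENTHIC),
    ("LTA", "long turfing algae", BENTHIC),
    ("SC", "scleractinian corals", BENTHIC),
    ("OCT", "octocorals", BENTHIC),
    ("SP", "sponges", BENTHIC),
    ("SAND", "sand", BENTHIC),
    ("RUB", "rubble", BENTHIC),
    ("CS", "consolidated substrate", BENTHIC),
    ("SHAD", "shadow", QUALITY),
    ("TAPE", "transect tape", QUALITY),
    ("UNID", "unidentifiable", QUALITY),
]


@dataclass(frozen=True)
class LabelSchema:
    """A set of (code, name, category) labels; category is benthic or quality."""

    labels: tuple[tuple[str, str, str], ...] = field(
        default_factory=lambda: tuple(DEFAULT_LABELS)
    )

    def __post_init__(self) -> None:
        codes = [c for c, _, _ in self.labels]
        if len(set(codes)) != len(codes):
            raise ValueError("label codes must be unique")
        bad = {cat for _, _, cat in self.labels} - {BENTHIC, QUALITY}
        if bad:
            raise ValueError(f"unknown label categories: {sorted(bad)}")
        if not self.benthic_codes:
            raise ValueError("schema needs at least one benthic label")

    @property
    def codes(self) -> list[str]:
        return [c for c, _, _ in self.labels]

    @property
    def benthic_codes(self) -> list[str]:
        return [c for c, _, cat in self.labels if cat == BENTHIC]

    @property
    def quality_codes(self) -> list[str]:
        return [c for c, _, cat in self.labels if cat == QUALITY]

    def category(self, code: str) -> str:
        for c, _, cat in self.labels:
            if c == code:
                return cat
        raise KeyError(f"unknown label code: {code!r}")

    def name(self, code: str) -> str:
        for c, name, _ in self.labels:
            if c == code:
                return name
        raise KeyError(f"unknown label code: {code!r}")

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path) -> None:
        doc = [
            {"code": c, "name": n, "category": cat} for c, n, cat in self.labels
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "LabelSchema":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(tuple((d["code"], d["name"], d["category"]) for d in doc))


DEFAULT_SCHEMA = LabelSchema()
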