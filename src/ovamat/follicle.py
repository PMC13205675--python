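"""Follicle staging, immunofluorescence count arithmetic, and the Pub-score.

Staging follows the classical histological criteria: a primordial follicle is
a single oocyte surrounded by flattened pre-granulosa cells; a primary
follicle has a single mixed layer of cuboidal/squamous granulosa cells; a
secondary follicle has two or more cuboidal layers; an antral follicle has a
fluid-filled cavity.  Follicles whose oocyte nucleus is not visible in the
section are excluded from counting.  Rule precedence is fixed:
exclusion → antral → granulosa-shape rules.

The puberty score (Pub-score) grades peripubertal ovarian maturation from the
diameter class of the most advanced healthy antral follicle:

    SF  (< 250 µm)        → −5
    F1  (250–300 µm)      → −4
    F2  (300–350 µm]      → −3
    F3  (350–400 µm]      → −2
    F4  (> 400 µm)        → −1

The printed integer class bounds (250–300 / 301–350 / 351–400) are made total
over real-valued diameters by the half-open convention
250 ≤ d ≤ 300 → F1, 300 < d ≤ 350 → F2, 350 < d ≤ 400 → F3, d > 400 → F4,
which preserves every integer boundary assignment.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ovamat.errors import ParameterError

__all__ = [
    "FollicleRecord",
    "PubertyScoreResult",
    "IFCounts",
    "STAGES",
    "CLASS_SCORES",
    "classify_follicle",
    "diameter_class",
    "tally_stages",
    "derive_if_counts",
    "puberty_score",
]

STAGES = ("primordial", "primary", "secondary", "antral", "excluded")
GRANULOSA_SHAPES = ("flattened", "mixed_cuboidal_squamous", "cuboidal")

#: Fixed bijection between diameter class and Pub-score.
CLASS_SCORES = {"SF": -5, "F1": -4, "F2": -3, "F3": -2, "F4": -1}


@dataclass
class FollicleRecord:
    """One morphology-annotated follicle."""

    id: str
    nucleus_visible: bool = True
    granulosa_layers: int = 1
    granulosa_shape: str = "flattened"
    antrum_present: bool = False
    healthy: bool = True
    oocyte_diameter: Optional[float] = None
    follicle_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.granulosa_layers < 0:
            raise ParameterError(f"{self.id}: granulosa_layers must be >= 0")
        if self.granulosa_shape not in GRANULOSA_SHAPES:
            raise ParameterError(
                f"{self.id}: unknown granulosa_shape {self.granulosa_shape!r}"
            )
        for name in ("oocyte_diameter", "follicle_diameter"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{self.id}: {name} must be > 0")


@dataclass
class IFCounts:
    """MVH/ZP3 immunofluorescence counts for one section or ovary.

    MVH (DDX4) marks every oocyte, so the MVH+ count proxies total follicles;
    ZP3 is expressed in the zona pellucida of growing but not primordial
    follicles, so the ZP3+ count proxies growing follicles.
    """

    mvh_positive: int
    zp3_positive: int

    def __post_init__(self) -> None:
        if self.mvh_positive < 0 or self.zp3_positive < 0:
            raise ParameterError("IF counts must be non-negative")


@dataclass
class PubertyScoreResult:
    six_largest: list
    top_class: str
    score: int
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if CLASS_SCORES[self.top_class] != self.score:
            raise ParameterError("score does not match top_class")


def classify_follicle(rec: FollicleRecord) -> str:
    """Assign a stage label to one follicle record.

    Precedence: no visible nucleus → ``excluded``; antrum → ``antral``;
    otherwise the granulosa shape/layer rules.  A record that matches no
    shape rule (e.g. cuboidal with a single layer) is the nearest stage by
    shape: cuboidal+1 layer → primary (a mixed layer in transition).
    """
    if not rec.nucleus_visible:
        return "excluded"
    if rec.antrum_present:
        if rec.granulosa_shape == "flattened" and rec.granulosa_layers <= 1:
            warnings.warn(
                f"{rec.id}: antrum with a single flattened layer is "
                "inconsistent; classified antral",
                stacklevel=2,
            )
        return "antral"
    if rec.granulosa_shape == "flattened":
        return "primordial"
    if rec.granulosa_shape == "mixed_cuboidal_squamous":
        return "primary"
    # cuboidal
    return "secondary" if rec.granulosa_layers >= 2 else "primary"


def tally_stages(records: Iterable[FollicleRecord]) -> dict:
    """Count follicles per stage over non-excluded records.

    Excluded records are reported separately so that
    sum(stage counts) + excluded == input size.
    """
    counts = Counter()
    total = 0
    for rec in records:
        counts[classify_follicle(rec)] += 1
        total += 1
    out = {s: counts.get(s, 0) for s in STAGES if s != "excluded"}
    out["excluded"] = counts.get("excluded", 0)
    out["total"] = total
    return out


def derive_if_counts(c: IFCounts, label_policy: str = "paper_literal") -> dict:
    """Derive follicle-pool sizes from MVH/ZP3 immunofluorescence counts.

    total = MVH+; growing = ZP3+; difference = MVH+ − ZP3+.  The label given
    to the difference is a policy choice because the marker semantics (ZP3
    marks growing, hence the difference should be the primordial pool) differ
    from the literal counting sentence used in neonatal-culture work (the
    difference called primary):

    * ``"paper_literal"`` (default) — difference labeled ``primary``.
    * ``"zp3_semantics"`` — difference labeled ``primordial``.

    A negative difference (ZP3+ exceeding MVH+) is biologically inconsistent;
    it is reported as 0 with a warning rather than failing.
    """
    if label_policy not in ("paper_literal", "zp3_semantics"):
        raise ParameterError(f"unknown label_policy {label_policy!r}")
    diff = c.mvh_positive - c.zp3_positive
    warnings_list = []
    if diff < 0:
        warnings_list.append(
            f"ZP3+ count ({c.zp3_positive}) exceeds MVH+ count "
            f"({c.mvh_positive}); difference reported as 0"
        )
        diff = 0
    label = "primary" if label_policy == "paper_literal" else "primordial"
    return {
        "total": c.mvh_positive,
        "growing": c.zp3_positive,
        "difference": diff,
        "difference_label": label,
        "warnings": warnings_list,
    }


def diameter_class(d: float) -> str:
    """Diameter class of a single antral follicle (µm).

    SF < 250; F1 250 ≤ d ≤ 300; F2 300 < d ≤ 350; F3 350 < d ≤ 400;
    F4 > 400.
    """
    if not d > 0:
        raise ParameterError("diameter must be > 0")
    if d < 250:
        return "SF"
    if d <= 300:
        return "F1"
    if d <= 350:
        return "F2"
    if d <= 400:
        return "F3"
    return "F4"


def puberty_score(
    records: Sequence[FollicleRecord], stages: Optional[Sequence[str]] = None
) -> PubertyScoreResult:
    """Pub-score of an ovary from its healthy antral follicle diameters.

    Selects healthy antral follicles (stage from ``classify_follicle`` unless
    ``stages`` supplies labels), measures the six largest diameters, and maps
    the class of the single largest to the score (SF → −5 … F4 → −1).  Fewer
    than six healthy antral follicles is allowed with a warning; none at all
    yields SF / −5 with flag ``no_antral``.
    """
    records = list(records)
    if stages is None:
        stages = [classify_follicle(r) for r in records]
    elif len(stages) != len(records):
        raise ParameterError("stages must align with records")

    bad = [
        r.id
        for r in records
        if r.follicle_diameter is not None and not r.follicle_diameter > 0
    ]
    if bad:
        raise ParameterError(f"non-positive diameters for records: {bad}")

    warnings_list = []
    diameters = []
    for rec, stage in zip(records, stages):
        if stage != "antral" or not rec.healthy:
            continue
        if rec.follicle_diameter is None:
            raise ParameterError(f"{rec.id}: antral follicle lacks a diameter")
        diameters.append(rec.follicle_diameter)

    if not diameters:
        warnings_list.append("no_antral")
        return PubertyScoreResult([], "SF", -5, warnings_list)

    six = sorted(diameters, reverse=True)[:6]
    if len(six) < 6:
        warnings_list.append(f"only {len(six)} healthy antral follicles")
    top = diameter_class(six[0])
    return PubertyScoreResult(six, top, CLASS_SCORES[top], warnings_list)
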