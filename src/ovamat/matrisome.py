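"""Matrisome categorization, overlap sets, DEG filtering and concordance.

The matrisome — the full complement of ECM and ECM-associated proteins — is
organized into two divisions and six categories:

    core matrisome        : collagens, proteoglycans, glycoproteins
    matrisome-associated  : ECM regulators, ECM-affiliated, secreted factors

Gene/protein lists are annotated by case-insensitive exact match against a
MatrisomeDB-style reference table; unmatched identifiers are labeled
non-matrisome.  Cross-species comparisons are exact set algebra over
case-folded identifier sets (all 2^s − 1 Venn regions).  Differential
expression uses the strict criterion |log2FC| > 1 and p < 0.05, and the
nine-quadrant concordance classifies each gene by its joint mRNA/protein
significance state (down / unchanged / up per axis).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ovamat.errors import FormatError, ParameterError

__all__ = [
    "CORE_CATEGORIES",
    "ASSOCIATED_CATEGORIES",
    "MatrisomeReference",
    "AnnotationResult",
    "load_reference",
    "annotate_list",
    "overlap_sets",
    "deg_filter",
    "nine_quadrant",
    "pearson_r",
]

CORE_CATEGORIES = ("collagens", "proteoglycans", "glycoproteins")
ASSOCIATED_CATEGORIES = ("ECM regulators", "ECM-affiliated", "secreted factors")
ALL_CATEGORIES = CORE_CATEGORIES + ASSOCIATED_CATEGORIES

_CATEGORY_DIVISION = {
    **{c: "core matrisome" for c in CORE_CATEGORIES},
    **{c: "matrisome-associated" for c in ASSOCIATED_CATEGORIES},
}


@dataclass
class MatrisomeReference:
    """Identifier → (division, category) map, keys case-folded."""

    entries: Dict[str, tuple]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for ident, (division, category) in self.entries.items():
            if category not in ALL_CATEGORIES:
                raise FormatError(f"{ident}: unknown category {category!r}")
            if _CATEGORY_DIVISION[category] != division:
                raise FormatError(
                    f"{ident}: category {category!r} is inconsistent with "
                    f"division {division!r}"
                )
        if not self.entries:
            raise FormatError("matrisome reference is empty")

    def category_of(self, identifier: str):
        hit = self.entries.get(identifier.casefold())
        return hit[1] if hit else None


@dataclass
class AnnotationResult:
    counts: Dict[str, int]
    percentages: Dict[str, float]
    non_matrisome: int
    input_size: int
    duplicates_collapsed: int = 0

    @property
    def matrisome_total(self) -> int:
        return sum(self.counts.values())


def load_reference(path) -> MatrisomeReference:
    """Load a matrisome reference CSV (columns: identifier, division, category).

    Duplicate identifiers (after case-folding) and category/division
    inconsistencies raise a :class:`FormatError` naming the offenders.
    """
    df = pd.read_csv(path)
    required = {"identifier", "division", "category"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"reference must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise FormatError("matrisome reference file has no entries")
    keys = df["identifier"].astype(str).str.casefold()
    dupes = keys[keys.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"duplicate identifiers in reference: {dupes}")
    entries = {
        k: (str(d).strip(), str(c).strip())
        for k, d, c in zip(keys, df["division"], df["category"])
    }
    return MatrisomeReference(entries)


def annotate_list(ids: Sequence[str], ref: MatrisomeReference) -> AnnotationResult:
    """Categorize an identifier list against a matrisome reference.

    Matching is case-folded exact; duplicates in the input are collapsed
    before counting (reported).  Percentages are per-category fractions of
    the matrisome total (not of the whole input), summing to 100.
    """
    if len(ids) == 0:
        raise ParameterError("identifier list is empty")
    folded = []
    seen = set()
    for i in ids:
        k = str(i).casefold()
        if k not in seen:
            seen.add(k)
            folded.append(k)
    dup = len(ids) - len(folded)

    counts = {c: 0 for c in ALL_CATEGORIES}
    non = 0
    for k in folded:
        hit = ref.entries.get(k)
        if hit is None:
            non += 1
        else:
            counts[hit[1]] += 1
    total = sum(counts.values())
    if total:
        pct = {c: 100.0 * n / total for c, n in counts.items()}
    else:
        pct = {c: 0.0 for c in counts}
    return AnnotationResult(counts, pct, non, len(folded), dup)


def overlap_sets(lists: Mapping[str, Iterable[str]]) -> dict:
    """All Venn regions over per-species identifier sets.

    Every identifier is case-folded.  For s species the 2^s − 1 exclusive
    regions are keyed by the frozenset of member species; counts sum to the
    size of the union.

    Returns
    -------
    dict with keys ``regions`` (region tuple → count), ``membership``
    (region tuple → sorted identifiers), ``union_size``, and
    ``per_species`` sizes.
    """
    if not lists:
        raise ParameterError("no sets supplied")
    sets = {
        name: {str(i).casefold() for i in ids} for name, ids in lists.items()
    }
    names = sorted(sets)
    membership: Dict[tuple, list] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            membership[combo] = []
    union = set().union(*sets.values())
    for ident in union:
        present = tuple(n for n in names if ident in sets[n])
        membership[present].append(ident)
    for v in membership.values():
        v.sort()
    return {
        "regions": {k: len(v) for k, v in membership.items()},
        "membership": membership,
        "union_size": len(union),
        "per_species": {n: len(sets[n]) for n in names},
    }


def deg_filter(
    table: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fc_col: str = "log2fc",
    p_col: str = "p",
) -> dict:
    """Differentially-expressed subset under |log2FC| > t and p < α.

    Both inequalities are strict, so a record exactly at the fold-change
    threshold is excluded.  Returns the surviving subset plus up/down counts.
    """
    for col in (fc_col, p_col):
        if col not in table.columns:
            raise ParameterError(f"table lacks column {col!r}")
    fc = table[fc_col].to_numpy(dtype=float)
    p = table[p_col].to_numpy(dtype=float)
    if not np.isfinite(fc).all():
        raise ParameterError("fold changes must be finite")
    keep = (np.abs(fc) > fc_threshold) & (p < p_threshold)
    subset = table.loc[keep]
    up = int(((fc > fc_threshold) & (p < p_threshold)).sum())
    down = int(((fc < -fc_threshold) & (p < p_threshold)).sum())
    return {"subset": subset, "n": int(keep.sum()), "up": up, "down": down}


def _axis_state(fc: np.ndarray, p: np.ndarray, t: float, alpha: float):
    """0 = down, 1 = unchanged, 2 = up (per the strict DEG criterion)."""
    state = np.ones(fc.shape, dtype=int)
    sig = p < alpha
    state[(fc < -t) & sig] = 0
    state[(fc > t) & sig] = 2
    return state


def nine_quadrant(
    pairs: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> dict:
    """Nine-quadrant mRNA–protein concordance.

    Each axis state is down (log2FC < −t and p < α), up (log2FC > t and
    p < α) or unchanged (otherwise).  Quadrant index = 3·mRNA_state +
    protein_state + 1 with states ordered down(0) / unchanged(1) / up(2), so
    quadrant 1 = both down, 5 = both unchanged, 9 = both up.  Pearson r is
    computed over all supplied pairs.

    Expects columns ``identifier, log2fc_mrna, p_mrna, log2fc_protein,
    p_protein``.
    """
    needed = ["log2fc_mrna", "p_mrna", "log2fc_protein", "p_protein"]
    for col in needed:
        if col not in pairs.columns:
            raise ParameterError(f"pairs table lacks column {col!r}")
    pv = pairs[["p_mrna", "p_protein"]].to_numpy(dtype=float)
    if ((pv < 0) | (pv > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = _axis_state(
        pairs["log2fc_mrna"].to_numpy(dtype=float),
        pairs["p_mrna"].to_numpy(dtype=float),
        fc_threshold,
        p_threshold,
    )
    pr = _axis_state(
        pairs["log2fc_protein"].to_numpy(dtype=float),
        pairs["p_protein"].to_numpy(dtype=float),
        fc_threshold,
        p_threshold,
    )
    quadrant = 3 * m + pr + 1
    counts = {q: int((quadrant == q).sum()) for q in range(1, 10)}
    try:
        r = pearson_r(
            pairs["log2fc_mrna"].to_numpy(dtype=float),
            pairs["log2fc_protein"].to_numpy(dtype=float),
        )
    except ParameterError:
        r = float("nan")  # degenerate (tiny or zero-variance) input
    out = pairs.copy()
    out["quadrant"] = quadrant
    return {
        "assignments": out,
        "counts": counts,
        "pearson_r": r,
        "n": len(pairs),
    }


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ParameterError("Pearson r needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ParameterError("Pearson r undefined for zero-variance input")
    return float((xc * yc).sum() / denom)
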