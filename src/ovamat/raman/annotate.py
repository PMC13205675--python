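"""Peak detection and label assignment for unmixed component spectra.

A component spectrum is annotated by detecting local maxima (prominence
based) and matching them against a user-supplied reference table mapping a
label (e.g. "collagen", "GAG") to its characteristic peak positions.  The
label with the highest fraction of matched reference peaks wins; a tie, or a
best fraction below the minimum, leaves the component unassigned.

A reference table with generic literature positions for collagen and
glycosaminoglycans ships with the package as an editable CSV
(``data/raman_reference_peaks_literature.csv``); it is a starting point, not
instrument truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from ovamat.errors import ParameterError
from ovamat.raman.types import ComponentSet

__all__ = ["PeakAnnotation", "annotate_component", "load_reference_peaks"]


@dataclass
class PeakAnnotation:
    component_index: int
    detected_peaks: List[Tuple[float, float]]  # (position cm^-1, prominence)
    assigned_label: str
    reference_used: str
    match_fractions: Dict[str, float] = field(default_factory=dict)
    tie: bool = False


def load_reference_peaks(path=None) -> Dict[str, List[float]]:
    """Load a label → peak-positions table from CSV (columns: label, position).

    Without a path, the bundled literature-defaults table is used.
    """
    if path is None:
        path = resources.files("ovamat.data").joinpath(
            "raman_reference_peaks_literature.csv"
        )
    df = pd.read_csv(path)
    if not {"label", "position"}.issubset(df.columns):
        raise ParameterError("peak table needs columns: label, position")
    out: Dict[str, List[float]] = {}
    for label, grp in df.groupby("label"):
        out[str(label)] = sorted(float(v) for v in grp["position"])
    return out


def annotate_component(
    cs: ComponentSet,
    component_index: int,
    reference_peaks: Dict[str, Sequence[float]],
    tolerance: float = 10.0,
    min_match_fraction: float = 0.5,
    min_prominence_frac: float = 0.05,
    reference_name: str = "user",
) -> PeakAnnotation:
    """Assign a chemical label to one unmixed component.

    Parameters
    ----------
    tolerance : float
        Maximum |detected − reference| distance (cm⁻¹) counting as a match.
    min_match_fraction : float
        Best label must match at least this fraction of its reference peaks.
    min_prominence_frac : float
        Peak-detection prominence threshold as a fraction of the component's
        maximum intensity.
    """
    if not 0 <= component_index < cs.k:
        raise ParameterError(f"component index {component_index} out of range")
    if not reference_peaks:
        raise ParameterError("reference peak table is empty")
    y = cs.W[:, component_index]
    w = cs.wavenumbers
    peak_max = float(y.max())
    if peak_max <= 0:
        return PeakAnnotation(
            component_index, [], "unassigned", reference_name
        )
    idx, props = signal.find_peaks(y, prominence=min_prominence_frac * peak_max)
    detected = [
        (float(w[i]), float(p)) for i, p in zip(idx, props["prominences"])
    ]
    positions = np.array([p for p, _ in detected])

    fractions: Dict[str, float] = {}
    for label, refs in reference_peaks.items():
        refs = np.asarray(list(refs), dtype=float)
        if refs.size == 0:
            fractions[label] = 0.0
            continue
        if positions.size == 0:
            fractions[label] = 0.0
        else:
            hit = (
                np.abs(refs[:, None] - positions[None, :]).min(axis=1)
                <= tolerance
            )
            fractions[label] = float(hit.mean())

    best = max(fractions.values())
    winners = [lab for lab, f in fractions.items() if f == best]
    tie = len(winners) > 1 and best > 0
    if best < min_match_fraction or tie or best == 0:
        label = "unassigned"
    else:
        label = winners[0]
    return PeakAnnotation(
        component_index, detected, label, reference_name, fractions, tie
    )
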