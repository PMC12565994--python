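"""Chemical shifts from shielding tensors, linear scaling, peak assignment,
and conformer-group concentration ratios from peak areas.

The chain mirrors how a GIAO/NMR conformer study is analysed:

1. isotropic shielding = mean diagonal of the 3x3 tensor;
2. chemical shift = reference (TMS) shielding minus the nucleus' shielding;
3. a per-nucleus linear rescaling ``scaled = a * theoretical + b`` fitted by
   ordinary least squares against experiment;
4. assignment of experimental peaks to (atom, conformer set) pairs;
5. the concentration ratio of the two conformer groups from the areas of
   peaks resolved between the groups.

Peak assignment works on *clusters*: within one atom, conformers whose
scaled shifts agree to better than the spectral resolution produce a single
peak, so the atom's shifts are first merged by single-linkage clustering.
Sorted experimental peaks are then aligned to sorted cluster centroids by an
order-preserving minimum-cost matching (dynamic programming with a gap
penalty equal to the matching tolerance).  Preserving shift order is what a
spectroscopist does when walking through a spectrum region by region; it
keeps an atom's split pair attached to the correct two peaks even when an
unrelated atom's shift happens to fall numerically closer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .types import ExperimentalPeak, ShieldingTensor, ValidationError

__all__ = [
    "isotropic_shielding",
    "chemical_shift",
    "fit_linear_scaling",
    "apply_scaling",
    "ScalingFit",
    "cluster_shifts",
    "assign_peaks",
    "AssignmentRow",
    "AssignmentTable",
    "group_ratio_from_areas",
    "GroupRatioResult",
    "InsufficientDataError",
    "DEFAULT_TOLERANCE_PPM",
    "DEFAULT_RESOLUTION_PPM",
]

#: Default |experimental - theoretical| matching tolerance per nucleus (ppm).
DEFAULT_TOLERANCE_PPM = {"13C": 2.0, "1H": 0.3}

#: Default resolution below which one atom's conformer shifts merge into one
#: peak (ppm); an order of magnitude apart for the two nuclei, like the
#: shift scales themselves.
DEFAULT_RESOLUTION_PPM = {"13C": 0.5, "1H": 0.1}


class InsufficientDataError(ValueError):
    """Raised when no atom provides a resolved conformer-group peak pair."""


def isotropic_shielding(tensor: ShieldingTensor | np.ndarray) -> float:
    """Isotropic shielding in ppm: the mean of the three diagonal components."""
    if isinstance(tensor, ShieldingTensor):
        return tensor.isotropic
    comp = np.asarray(tensor, dtype=float)
    if comp.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 tensor, got shape {comp.shape}")
    return float(np.trace(comp) / 3.0)


def chemical_shift(iso_conformer: float, iso_reference: float) -> float:
    """Chemical shift in ppm: reference shielding minus nucleus shielding."""
    if not (math.isfinite(iso_conformer) and math.isfinite(iso_reference)):
        raise ValidationError("shieldings must be finite")
    return iso_reference - iso_conformer


# ---------------------------------------------------------------------------
# Linear scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingFit:
    """Least-squares fit of experimental vs theoretical shifts, per nucleus."""

    nucleus: str
    a: float
    b: float
    n_points: int
    rmse: float
    r_squared: float


def fit_linear_scaling(
    pairs: Sequence[tuple[float, float]], nucleus: str
) -> ScalingFit:
    """Ordinary least squares of experimental on theoretical shifts.

    ``pairs`` are (theoretical ppm, experimental ppm).  The two nuclei are
    always fitted separately — their references and shift ranges differ by
    an order of magnitude, so a joint fit would be dominated by 13C.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("need at least 2 (theoretical, experimental) pairs")
    theor, exp = arr[:, 0], arr[:, 1]
    if np.ptp(theor) == 0:
        raise ValidationError(
            "all theoretical values identical: scaling fit is singular"
        )
    result = stats.linregress(theor, exp)
    predicted = result.slope * theor + result.intercept
    rmse = float(np.sqrt(np.mean((exp - predicted) ** 2)))
    return ScalingFit(
        nucleus=nucleus,
        a=float(result.slope),
        b=float(result.intercept),
        n_points=int(arr.shape[0]),
        rmse=rmse,
        r_squared=float(result.rvalue**2),
    )


def apply_scaling(shifts, fit: ScalingFit, nucleus: str | None = None):
    """Apply ``scaled = a * shift + b`` elementwise.

    Accepts a scalar, an array, or a mapping; returns the same shape.  When
    ``nucleus`` is given it must match the fit's nucleus.
    """
    if nucleus is not None and nucleus != fit.nucleus:
        raise ValidationError(
            f"fit is for {fit.nucleus} but shifts are {nucleus}"
        )
    if isinstance(shifts, Mapping):
        return {k: fit.a * float(v) + fit.b for k, v in shifts.items()}
    arr = np.asarray(shifts, dtype=float)
    scaled = fit.a * arr + fit.b
    return float(scaled) if np.isscalar(shifts) or arr.ndim == 0 else scaled


# ---------------------------------------------------------------------------
# Peak assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftCluster:
    """One predicted peak: an atom and the conformers merged into it."""

    atom: str
    conformers: tuple[Hashable, ...]
    shifts: dict[Hashable, float] = field(hash=False)

    @property
    def centroid(self) -> float:
        return float(np.mean(list(self.shifts.values())))


def cluster_shifts(
    per_conformer: Mapping[Hashable, float], resolution: float, atom: str = ""
) -> list[ShiftCluster]:
    """Merge one atom's conformer shifts by single-linkage at ``resolution``.

    Conformers whose shifts form a chain with consecutive gaps <= resolution
    produce one predicted peak.  Returned sorted by descending centroid.
    """
    if resolution < 0:
        raise ValidationError("resolution must be >= 0")
    items = sorted(per_conformer.items(), key=lambda kv: (-kv[1], str(kv[0])))
    clusters: list[list[tuple[Hashable, float]]] = []
    for cid, value in items:
        if clusters and clusters[-1][-1][1] - value <= resolution:
            clusters[-1].append((cid, value))
        else:
            clusters.append([(cid, value)])
    return [
        ShiftCluster(
            atom=atom,
            conformers=tuple(sorted((c for c, _ in group), key=str)),
            shifts=dict(group),
        )
        for group in clusters
    ]


@dataclass(frozen=True)
class AssignmentRow:
    """One experimental peak matched to an atom and a conformer set."""

    peak: ExperimentalPeak
    atom: str
    conformers: tuple[Hashable, ...]
    theoretical: dict[Hashable, float] = field(hash=False)
    delta: float = 0.0
    within_tolerance: bool = True


@dataclass
class AssignmentTable:
    """Result of matching experimental peaks against predicted peaks.

    ``rows`` hold the matched peaks; ``unassigned`` the peaks no predicted
    peak could be aligned with; ``unmatched_clusters`` the predicted peaks
    left without an experimental partner.  Rows whose |delta| exceeds the
    tolerance are kept (the alignment accepts matches up to twice the
    tolerance before preferring a gap) but flagged ``within_tolerance=False``.
    """

    rows: list[AssignmentRow]
    unassigned: list[ExperimentalPeak]
    unmatched_clusters: list[ShiftCluster]
    nucleus: str
    tolerance: float

    def row_for(self, shift: float, atol: float = 1e-9) -> AssignmentRow:
        for row in self.rows:
            if abs(row.peak.shift - shift) <= atol:
                return row
        raise KeyError(f"no assigned peak at {shift} ppm")


def assign_peaks(
    peaks: Sequence[ExperimentalPeak],
    theoretical: Mapping[tuple[str, Hashable], float],
    tolerance: float | None = None,
    resolution: float | None = None,
) -> AssignmentTable:
    """Assign experimental peaks to (atom, conformer set) predicted peaks.

    ``theoretical`` maps (atom label, conformer id) to the scaled
    theoretical shift in ppm.  Per-atom shifts are clustered at
    ``resolution`` into predicted peaks, then peaks and predicted peaks are
    aligned in shift order by a minimum-cost monotone matching: matching a
    peak to a cluster costs |experimental - centroid|, skipping either side
    costs ``tolerance``.  A match is therefore accepted exactly when it is
    cheaper than leaving both sides unmatched, i.e. up to 2x tolerance;
    rows beyond the tolerance itself are flagged.  The procedure is fully
    deterministic: ties prefer matching, then skipping the peak.

    Peaks with no partner are reported as unassigned, not as errors.
    """
    if not theoretical:
        raise ValidationError("theoretical shift map is empty")
    nuclei = {p.nucleus for p in peaks}
    if len(nuclei) > 1:
        raise ValidationError(
            f"assign one nucleus at a time, got {sorted(nuclei)}"
        )
    nucleus = nuclei.pop() if nuclei else "13C"
    if tolerance is None:
        tolerance = DEFAULT_TOLERANCE_PPM[nucleus]
    if resolution is None:
        resolution = DEFAULT_RESOLUTION_PPM[nucleus]
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")

    if not peaks:
        return AssignmentTable([], [], [], nucleus, tolerance)

    per_atom: dict[str, dict[Hashable, float]] = {}
    for (atom, cid), value in theoretical.items():
        per_atom.setdefault(str(atom), {})[cid] = float(value)
    clusters: list[ShiftCluster] = []
    for atom in sorted(per_atom):  # sorted for determinism
        clusters.extend(cluster_shifts(per_atom[atom], resolution, atom=atom))

    # order both sides descending in shift, stable tie-break by label
    peak_order = sorted(
        range(len(peaks)), key=lambda i: (-peaks[i].shift, peaks[i].label)
    )
    clusters.sort(key=lambda c: (-c.centroid, c.atom))

    n, m = len(peak_order), len(clusters)
    gap = float(tolerance)
    cost = np.zeros((n + 1, m + 1))
    cost[1:, 0] = gap * np.arange(1, n + 1)
    cost[0, 1:] = gap * np.arange(1, m + 1)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 match, 1 skip peak, 2 skip cluster
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        peak_shift = peaks[peak_order[i - 1]].shift
        for j in range(1, m + 1):
            match = cost[i - 1, j - 1] + abs(peak_shift - clusters[j - 1].centroid)
            skip_peak = cost[i - 1, j] + gap
            skip_cluster = cost[i, j - 1] + gap
            best, which = match, 0
            if skip_peak < best:
                best, which = skip_peak, 1
            if skip_cluster < best:
                best, which = skip_cluster, 2
            cost[i, j], move[i, j] = best, which

    rows: list[AssignmentRow] = []
    unassigned: list[ExperimentalPeak] = []
    unmatched: list[ShiftCluster] = []
    i, j = n, m
    while i > 0 or j > 0:
        which = move[i, j]
        if which == 0:
            peak = peaks[peak_order[i - 1]]
            cluster = clusters[j - 1]
            delta = min(abs(peak.shift - v) for v in cluster.shifts.values())
            rows.append(
                AssignmentRow(
                    peak=peak,
                    atom=cluster.atom,
                    conformers=cluster.conformers,
                    theoretical=dict(cluster.shifts),
                    delta=delta,
                    within_tolerance=delta <= tolerance,
                )
            )
            i, j = i - 1, j - 1
        elif which == 1:
            unassigned.append(peaks[peak_order[i - 1]])
            i -= 1
        else:
            unmatched.append(clusters[j - 1])
            j -= 1
    rows.reverse()
    unassigned.reverse()
    unmatched.reverse()
    return AssignmentTable(rows, unassigned, unmatched, nucleus, tolerance)


# ---------------------------------------------------------------------------
# Conformer-group ratio from peak areas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupRatioResult:
    """Concentration ratio of conformer group A to group B from peak areas.

    ``ratio`` is the median of the per-atom ratios; atoms lacking a resolved
    (A-peak, B-peak) pair with areas are listed in ``excluded``.
    """

    ratio: float
    per_atom: dict[str, float]
    excluded: tuple[str, ...]


def group_ratio_from_areas(
    assignments: AssignmentTable,
    group_a: Iterable[Hashable],
    group_b: Iterable[Hashable],
) -> GroupRatioResult:
    """Estimate [group A]/[group B] from areas of conformer-split peaks.

    For every atom with one assigned peak covering only group-A conformers
    and another covering only group-B conformers (both with areas), the atom
    contributes area_A / area_B; areas are summed when an atom has several
    peaks on one side.  The overall estimate is the median over atoms —
    robust to a single mis-assigned pair.
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if a & b:
        raise ValidationError(f"groups overlap: {sorted(map(str, a & b))}")

    atoms: dict[str, dict[str, float]] = {}
    for row in assignments.rows:
        conformers = set(row.conformers)
        if row.peak.area is None:
            continue
        if conformers <= a:
            side = "A"
        elif conformers <= b:
            side = "B"
        else:
            continue  # peak merges both groups; carries no ratio information
        bucket = atoms.setdefault(row.atom, {"A": 0.0, "B": 0.0})
        bucket[side] += row.peak.area

    per_atom: dict[str, float] = {}
    excluded: list[str] = []
    for atom, bucket in sorted(atoms.items()):
        if bucket["A"] > 0 and bucket["B"] > 0:
            per_atom[atom] = bucket["A"] / bucket["B"]
        elif bucket["B"] > 0:
            per_atom[atom] = 0.0  # group A genuinely absent for this atom
        else:
            excluded.append(atom)
    if not per_atom:
        raise InsufficientDataError(
            "no atom has a resolved pair of group-A and group-B peaks with areas"
        )
    return GroupRatioResult(
        ratio=float(np.median(list(per_atom.values()))),
        per_atom=per_atom,
        excluded=tuple(excluded),
    )
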