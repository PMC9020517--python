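"""Weighted chemical shift perturbation (CSP) mapping.

The combined amide perturbation between corresponding peaks of two
spectra is

    delta_omega = sqrt( ( (d1H)^2 + (1/25)(d15N)^2 ) / 2 )   [ppm]

where the 1/25 factor rescales the wider 15N shift dispersion onto the
1H scale.  Residues are classified against two data-driven thresholds,
the profile mean and the mean plus one standard deviation, mirroring
how CSP bar plots are conventionally annotated.

The same weighted metric drives :func:`transfer_assignment`, which maps
an assigned spectrum onto an unassigned, near-identical one (e.g. a
phosphoprotein onto its non-hydrolyzable phosphonate analog) by a
globally optimal one-to-one peak matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import EmptyProfileError, ParameterError
from .peaks import Peak, PeakList, State

__all__ = [
    "weighted_shift_distance",
    "CSPProfile",
    "AssignmentTransfer",
    "compute_csp",
    "classify_csp",
    "transfer_assignment",
]

#: 15N shifts are down-weighted by this factor inside the squared sum.
N15_WEIGHT = 1.0 / 25.0

BELOW_MEAN = "below_mean"
ABOVE_MEAN = "above_mean"
ABOVE_MEAN_PLUS_SD = "above_mean_plus_sd"


def weighted_shift_distance(delta_h: float, delta_n: float) -> float:
    """Weighted 1H/15N shift distance in ppm (vectorizes over arrays)."""
    return np.sqrt((np.asarray(delta_h) ** 2 + N15_WEIGHT * np.asarray(delta_n) ** 2) / 2.0)


@dataclass
class CSPProfile:
    """Per-residue weighted shift perturbations between two spectra.

    ``entries`` has one row per residue observed in both spectra, with
    columns ``residue_index, aa, delta_h, delta_n, delta_omega``;
    residues observed in only one spectrum are listed in ``missing``.
    """

    reference_spectrum: str
    query_spectrum: str
    entries: pd.DataFrame
    mean_threshold: float
    sd_threshold: float
    missing: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.entries["delta_omega"] < 0).any():
            raise ValueError("delta_omega must be non-negative")
        if self.sd_threshold < self.mean_threshold:
            raise ValueError("sd_threshold must be >= mean_threshold")
        overlap = set(self.entries["residue_index"]) & self.missing
        if overlap:
            raise ValueError(f"residues both observed and missing: {sorted(overlap)}")


def compute_csp(
    reference: PeakList,
    query: PeakList,
    ref_state: State | str = State.SINGLE,
    query_state: State | str = State.SINGLE,
    ddof: int = 1,
) -> CSPProfile:
    """CSP profile of ``query`` (selected state) against ``reference``.

    Ambiguous-state peaks never contribute.  Thresholds are the mean and
    mean + 1 standard deviation (``ddof=1``, sample SD; set ``ddof=0``
    for the population convention) over the observed residues only.
    """
    ref_state, query_state = State(ref_state), State(query_state)
    if State.AMBIGUOUS in (ref_state, query_state):
        raise ParameterError("ambiguous peaks cannot be used as a state selector")
    ref_peaks = reference.select(ref_state)
    query_peaks = query.select(query_state)
    common = sorted(set(ref_peaks) & set(query_peaks))
    if not common:
        raise EmptyProfileError(
            f"no overlapping residues between {reference.spectrum!r} and {query.spectrum!r}"
        )
    rows = []
    for idx in common:
        rp, qp = ref_peaks[idx], query_peaks[idx]
        dh = qp.shift_h - rp.shift_h
        dn = qp.shift_n - rp.shift_n
        rows.append(
            {
                "residue_index": idx,
                "aa": rp.residue.aa,
                "delta_h": dh,
                "delta_n": dn,
                "delta_omega": float(weighted_shift_distance(dh, dn)),
            }
        )
    entries = pd.DataFrame(rows)
    omega = entries["delta_omega"].to_numpy()
    mean = float(omega.mean())
    sd = float(omega.std(ddof=ddof)) if len(omega) > ddof else 0.0
    missing = (set(ref_peaks) | set(query_peaks)) - set(common)
    return CSPProfile(
        reference_spectrum=reference.spectrum,
        query_spectrum=query.spectrum,
        entries=entries,
        mean_threshold=mean,
        sd_threshold=mean + sd,
        missing=missing,
    )


def classify_csp(profile: CSPProfile) -> pd.Series:
    """Strongest label per residue, indexed by residue number.

    ``above_mean`` means strictly above the profile mean;
    ``above_mean_plus_sd`` strictly above mean + 1 SD (and hence also
    above the mean, by threshold ordering).
    """
    if profile.entries.empty:
        raise EmptyProfileError("cannot classify an empty profile")
    omega = profile.entries.set_index("residue_index")["delta_omega"]
    labels = pd.Series(BELOW_MEAN, index=omega.index, name="label", dtype=object)
    labels[omega > profile.mean_threshold] = ABOVE_MEAN
    labels[omega > profile.sd_threshold] = ABOVE_MEAN_PLUS_SD
    return labels


@dataclass
class AssignmentTransfer:
    """Result of matching an unassigned spectrum onto an assigned one."""

    pairs: list[tuple[Peak, Peak, float]]  # (assigned, unassigned, distance)
    unmatched_assigned: list[Peak]
    unmatched_unassigned: list[Peak]
    cutoff: float

    def recovered_indices(self) -> dict[int, int]:
        """assigned residue index -> position of its partner in the unassigned list."""
        return {a.residue.index: i for i, (a, _, _) in enumerate(self.pairs)}


def transfer_assignment(
    assigned: PeakList, unassigned: PeakList, cutoff: float = 0.15
) -> AssignmentTransfer:
    """Optimal one-to-one peak matching under the weighted shift metric.

    Minimizes the total weighted distance over all one-to-one pairings
    (Hungarian assignment, hence deterministic and globally optimal),
    then dissolves any pair farther apart than ``cutoff`` (ppm, weighted
    scale) into the unmatched sets.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0, got {cutoff}")
    if not assigned.peaks or not unassigned.peaks:
        raise ParameterError("both peak lists must be non-empty")
    a_peaks = sorted(assigned.peaks, key=lambda p: (p.residue.index, p.state.value))
    u_peaks = sorted(unassigned.peaks, key=lambda p: (p.residue.index, p.state.value))
    cost = np.empty((len(a_peaks), len(u_peaks)))
    for i, ap in enumerate(a_peaks):
        for j, up in enumerate(u_peaks):
            cost[i, j] = weighted_shift_distance(
                ap.shift_h - up.shift_h, ap.shift_n - up.shift_n
            )
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_a, matched_u = set(), set()
    for i, j in zip(rows, cols):
        d = float(cost[i, j])
        if d <= cutoff:
            pairs.append((a_peaks[i], u_peaks[j], d))
            matched_a.add(i)
            matched_u.add(j)
    return AssignmentTransfer(
        pairs=pairs,
        unmatched_assigned=[p for i, p in enumerate(a_peaks) if i not in matched_a],
        unmatched_unassigned=[p for j, p in enumerate(u_peaks) if j not in matched_u],
        cutoff=cutoff,
    )


def profile_to_frame(profile: CSPProfile) -> pd.DataFrame:
    """Entries plus classification labels, ready for TSV export."""
    labels = classify_csp(profile)
    out = profile.entries.copy()
    out["label"] = labels.reindex(out["residue_index"]).to_numpy()
    return out
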