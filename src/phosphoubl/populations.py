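"""Relaxed/retracted conformer populations from relative peak heights.

For a residue whose relaxed-state (m) and retracted-state (n) peaks are
resolved, the retracted population is estimated from signal heights as

    f_n = I_n / (I_m + I_n)

and the relaxed fraction is its complement.  A construct-level estimate
averages f_n over a fixed panel of well-separated cross-peak pairs; the
package ships the three 17-residue panels used for pNEDD8, pUb and
nhpUb (the non-hydrolyzable phosphonate analog of pUb), validated at
load time against the mature sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .errors import MissingResidueError, UndefinedFractionError, ValidationError
from .peaks import ResidueId, parse_residue_token
from .sequences import SEQUENCES

__all__ = [
    "ConformerPair",
    "PopulationEstimate",
    "retracted_fraction",
    "population_summary",
    "load_residue_sets",
    "RESIDUE_SETS",
]


@dataclass(frozen=True)
class ConformerPair:
    """Resolved relaxed/retracted peak heights for one residue."""

    residue: ResidueId
    i_m: float
    i_n: float

    def __post_init__(self) -> None:
        if self.i_m < 0 or self.i_n < 0:
            raise ValidationError(f"negative peak height for {self.residue}")
        if self.i_m + self.i_n == 0:
            raise ValidationError(f"both heights zero for {self.residue}")


def retracted_fraction(pair: ConformerPair) -> float:
    """f_n = I_n / (I_m + I_n)."""
    total = pair.i_m + pair.i_n
    if total == 0:
        raise UndefinedFractionError(f"I_m + I_n = 0 for {pair.residue}")
    return pair.i_n / total


@dataclass
class PopulationEstimate:
    """Per-residue retracted fractions and their panel summary.

    ``sd_fn`` is the sample (n-1) standard deviation across residues;
    ``sem_fn`` the standard error of the mean, reported alongside
    because a printed "+/-" on a population can denote either spread.
    """

    per_residue: dict[ResidueId, float]
    mean_fn: float
    sd_fn: float
    sem_fn: float
    residue_set: list[ResidueId] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.per_residue)

    @property
    def mean_relaxed(self) -> float:
        return 1.0 - self.mean_fn


def population_summary(
    pairs: Iterable[ConformerPair],
    residue_set: Sequence[ResidueId] | None = None,
    mode: str = "per_residue",
) -> PopulationEstimate:
    """Panel-average retracted fraction.

    ``mode='per_residue'`` (default) computes f_n per residue and then
    averages — each resolved pair is one independent estimate of the
    population.  ``mode='pooled'`` sums heights over the panel first,
    which weights residues by intensity.
    """
    by_residue = {p.residue: p for p in pairs}
    if residue_set is None:
        selected = sorted(by_residue, key=lambda r: r.index)
    else:
        missing = [str(r) for r in residue_set if r not in by_residue]
        if missing:
            raise MissingResidueError(
                f"residue set members without a conformer pair: {', '.join(missing)}"
            )
        selected = list(residue_set)
    if not selected:
        raise MissingResidueError("no conformer pairs to summarize")
    fns = np.array([retracted_fraction(by_residue[r]) for r in selected])
    if mode == "pooled":
        tot_n = sum(by_residue[r].i_n for r in selected)
        tot = sum(by_residue[r].i_m + by_residue[r].i_n for r in selected)
        mean = tot_n / tot
    elif mode == "per_residue":
        mean = float(fns.mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sd = float(fns.std(ddof=1)) if len(fns) > 1 else 0.0
    return PopulationEstimate(
        per_residue={r: float(retracted_fraction(by_residue[r])) for r in selected},
        mean_fn=mean,
        sd_fn=sd,
        sem_fn=sd / np.sqrt(len(fns)),
        residue_set=selected,
    )


def write_pairs(pairs: Iterable[ConformerPair], path) -> None:
    """Conformer pairs as TSV (residue_index, aa, i_m, i_n)."""
    import pandas as pd

    pd.DataFrame(
        [
            {"residue_index": p.residue.index, "aa": p.residue.aa, "i_m": p.i_m, "i_n": p.i_n}
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[ConformerPair]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        ConformerPair(ResidueId(int(r.residue_index), str(r.aa)), float(r.i_m), float(r.i_n))
        for r in df.itertuples()
    ]


def load_residue_sets() -> dict[str, list[ResidueId]]:
    """Packaged cross-peak panels, validated against the sequences."""
    raw = json.loads(
        resources.files("phosphoubl.data").joinpath("residue_sets.json").read_text()
    )
    sets: dict[str, list[ResidueId]] = {}
    for name, spec in raw.items():
        seq = SEQUENCES[spec["sequence"]]
        residues = [parse_residue_token(tok) for tok in spec["residues"]]
        for r in residues:
            if seq[r.index - 1] != r.aa:
                raise ValidationError(
                    f"residue set {name!r}: {r} does not match sequence "
                    f"({spec['sequence']} position {r.index} is {seq[r.index - 1]})"
                )
        sets[name] = residues
    return sets


RESIDUE_SETS = load_residue_sets()
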