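"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator is the closed-loop partner of an analysis stage: it
draws data from the forward model the stage assumes, with the true
parameter recorded, so noise-free generation must be recovered exactly
and noisy generation within quantifiable bands.  The packaged default
scenarios encode the study conditions this package models:

* ``pnedd8`` — S65-phosphorylated NEDD8, 45 % relaxed state,
  interconversion rate 8.3 1/s, three state-ambiguous residues
  (D21/I36/G47 pattern);
* ``pub`` — phosphorylated ubiquitin, 56 % relaxed state, 2 1/s;
* ``nhpub`` — the non-hydrolyzable phosphonate analog of pUb, 12 %
  retracted state (the phosphonate's higher pKa leaves fewer molecules
  doubly deprotonated at physiological pH, disfavoring retraction).

Noise models: multiplicative log-normal for NMR peak heights and
peptide peak areas (positive quantities whose error scales with
signal); additive Gaussian in log2 space for protein LFQ intensities;
missing-not-at-random dropout as a logistic function of log2 intensity
(low-abundance proteins fall below the detection limit first).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_GROUPS, IntensityMatrix
from .errors import ParameterError
from .peaks import Peak, PeakList, ResidueId, State
from .populations import RESIDUE_SETS, ConformerPair
from .sequences import SEQUENCES, amide_observable_residues
from .zz import ZZSeries, simulate_zz

__all__ = [
    "Scenario",
    "AEMSTruth",
    "TargetedTruth",
    "GroundTruth",
    "load_scenarios",
    "SCENARIOS",
    "make_two_state_peaklists",
    "make_zz_fixture",
    "make_aems_matrix",
    "make_targeted_table",
    "ZZ_MIXING_TIMES",
]

#: Mixing times (s) of the ZZ-exchange experiment this package models.
ZZ_MIXING_TIMES = (0.02, 0.04, 0.06, 0.10)


@dataclass(frozen=True)
class Scenario:
    """NMR ground truth for one phosphoprotein construct."""

    name: str
    protein: str
    sequence: str  # key into sequences.SEQUENCES
    residue_set: str  # key into populations.RESIDUE_SETS
    relaxed_fraction: float
    k_conf: float  # 1/s
    r1: float  # 1/s
    noise_cv: float
    ambiguous_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.relaxed_fraction < 1.0:
            raise ParameterError("relaxed_fraction must be in (0,1)")

    @property
    def retracted_fraction(self) -> float:
        return 1.0 - self.relaxed_fraction


def load_scenarios() -> dict[str, Scenario]:
    raw = json.loads(
        resources.files("phosphoubl.data").joinpath("scenarios.json").read_text()
    )
    return {
        name: Scenario(
            name=name,
            protein=spec["protein"],
            sequence=spec["sequence"],
            residue_set=spec["residue_set"],
            relaxed_fraction=spec["relaxed_fraction"],
            k_conf=spec["k_conf"],
            r1=spec["r1"],
            noise_cv=spec["noise_cv"],
            ambiguous_residues=tuple(spec["ambiguous_residues"]),
        )
        for name, spec in raw.items()
    }


SCENARIOS = load_scenarios()


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


# --------------------------------------------------------------------------
# two-state peak lists


#: Residues whose retracted-state perturbation is planted large: the
#: C-terminal beta5-strand / 3-10-helix region, plus the two residues
#: hydrogen-bonded to S65 across the fold.
_RETRACTED_REGION = range(60, 73)
_HBOND_PARTNERS = (4, 45)
_NEAR_SITE = range(62, 69)  # relaxed-state perturbations stay local to S65


def _signed_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))


def make_two_state_peaklists(
    scenario: Scenario,
    seed: int | None = None,
    noise_cv: float | None = None,
    one_state_residues: tuple[int, ...] = (9, 23, 35),
    base_height: float = 1e6,
) -> tuple[PeakList, PeakList, list[ConformerPair]]:
    """Reference and two-state phosphoprotein peak lists plus pairs.

    The reference list holds single-state peaks at base shifts; the
    phosphoprotein list holds relaxed-state (m) peaks offset by a small
    near-site perturbation profile and retracted-state (n) peaks offset
    by a large profile concentrated on the C-terminal region (residues
    60-72) and the S65 hydrogen-bond partners, so the largest CSPs land
    where beta5-strand slippage puts them.  Heights realize the
    scenario's relaxed/retracted population ratio before noise.
    ``one_state_residues`` are emitted in the relaxed state only
    (incomplete state coverage, as real assignments have); ambiguous
    residues are emitted as one state-unassignable peak.
    """
    sequence = SEQUENCES[scenario.sequence]
    cv = scenario.noise_cv if noise_cv is None else noise_cv
    f_n = scenario.retracted_fraction
    rng = np.random.default_rng(seed)
    observable = amide_observable_residues(sequence)

    ref_peaks: list[Peak] = []
    phos_peaks: list[Peak] = []
    pairs: list[ConformerPair] = []
    for idx in observable:
        residue = ResidueId(idx, sequence[idx - 1])
        shift_h = float(rng.uniform(7.0, 9.5))
        shift_n = float(rng.uniform(105.0, 130.0))
        # retracted-state offsets: bounded so the region's smallest
        # combined perturbation beats everything outside it
        if idx in _RETRACTED_REGION:
            ret_dh = _signed_uniform(rng, 0.18, 0.35)
            ret_dn = _signed_uniform(rng, 1.2, 2.5)
        elif idx in _HBOND_PARTNERS:
            ret_dh = _signed_uniform(rng, 0.10, 0.15)
            ret_dn = _signed_uniform(rng, 0.6, 1.0)
        else:
            ret_dh = float(rng.uniform(-0.02, 0.02))
            ret_dn = float(rng.uniform(-0.10, 0.10))
        if idx in _NEAR_SITE:
            rel_dh = _signed_uniform(rng, 0.05, 0.12)
            rel_dn = _signed_uniform(rng, 0.30, 0.80)
        else:
            rel_dh = float(rng.uniform(-0.01, 0.01))
            rel_dn = float(rng.uniform(-0.05, 0.05))

        amp = base_height * float(_lognormal_factor(rng, 0.2, ()))
        ref_height = amp * float(_lognormal_factor(rng, cv, ()))
        ref_peaks.append(
            Peak(residue, State.SINGLE, shift_h, shift_n, ref_height)
        )
        if idx in scenario.ambiguous_residues:
            phos_peaks.append(
                Peak(
                    residue,
                    State.AMBIGUOUS,
                    shift_h + (rel_dh + ret_dh) / 2.0,
                    shift_n + (rel_dn + ret_dn) / 2.0,
                    amp * float(_lognormal_factor(rng, cv, ())),
                )
            )
            continue
        i_m = amp * (1.0 - f_n) * float(_lognormal_factor(rng, cv, ()))
        phos_peaks.append(
            Peak(residue, State.RELAXED, shift_h + rel_dh, shift_n + rel_dn, i_m)
        )
        if idx in one_state_residues:
            continue
        i_n = amp * f_n * float(_lognormal_factor(rng, cv, ()))
        phos_peaks.append(
            Peak(residue, State.RETRACTED, shift_h + ret_dh, shift_n + ret_dn, i_n)
        )
        pairs.append(ConformerPair(residue, i_m=i_m, i_n=i_n))

    reference = PeakList(
        protein=scenario.sequence,
        spectrum=f"hsqc_{scenario.sequence}",
        conditions={"ph": 7.4, "temperature_K": 298.0, "field_MHz": 800.0},
        peaks=ref_peaks,
        sequence_length=len(sequence),
    )
    phosphorylated = PeakList(
        protein=scenario.protein,
        spectrum=f"hsqc_{scenario.name}",
        conditions={"ph": 7.4, "temperature_K": 298.0, "field_MHz": 800.0},
        peaks=phos_peaks,
        sequence_length=len(sequence),
    )
    return reference, phosphorylated, pairs


# --------------------------------------------------------------------------
# ZZ-exchange fixture


def make_zz_fixture(
    scenario: Scenario,
    seed: int | None = None,
    noise_cv: float | None = None,
    t_mix=ZZ_MIXING_TIMES,
    panel: list[ResidueId] | None = None,
) -> list[ZZSeries]:
    """ZZ height series for the well-resolved residue panel.

    Default panel: the six residues with fully resolved auto- and
    cross-peaks in the pNEDD8 spectra (L2, I13, Y45, T55, L67, H68).
    Each residue gets its own amplitude and noise stream.
    """
    if panel is None:
        panel = RESIDUE_SETS["zz_panel"]
    cv = scenario.noise_cv if noise_cv is None else noise_cv
    ss = np.random.SeedSequence(seed)
    amp_rng = np.random.default_rng(ss.spawn(1)[0])
    sub_seeds = ss.generate_state(len(panel)) % (2**31)
    out = []
    for residue, sub in zip(panel, sub_seeds):
        amplitude = 1e6 * float(_lognormal_factor(amp_rng, 0.2, ()))
        out.append(
            simulate_zz(
                p_relaxed=scenario.relaxed_fraction,
                k_conf=scenario.k_conf,
                r1=scenario.r1,
                t_mix=t_mix,
                amplitude=amplitude,
                noise_cv=cv,
                seed=int(sub),
                residue=residue,
            )
        )
    return out


# --------------------------------------------------------------------------
# AE-MS intensity matrix


@dataclass(frozen=True)
class AEMSTruth:
    """Ground truth for the affinity-enrichment matrix generator.

    Planted interactor classes get an additive log2 enrichment
    ``effect`` in their preferred bait groups; ``bead_binder`` proteins
    are enriched in the bead control only (resin background).  Class
    sizes default to the composition of the family-overlap analysis
    this package reproduces (126 Ub-exclusive / 58 shared / 36
    NEDD8-exclusive interactors).
    """

    n_background: int = 250
    n_ub_only: int = 126
    n_shared: int = 58
    n_nedd8_only: int = 36
    n_bead_binder: int = 30
    n_reverse: int = 10
    n_contaminant: int = 10
    effect: float = 4.0  # log2 enrichment in preferred groups
    base_mean: float = 25.0  # log2 intensity
    base_sd: float = 2.0
    replicate_sd: float = 0.3  # additive log2 replicate noise
    replicates: int = 6  # 3 biological x 2 technical, treated as 6
    dropout: bool = True
    dropout_midpoint: float = 22.0  # log2 intensity of 50% detection
    dropout_scale: float = 1.0

    @property
    def class_sizes(self) -> dict[str, int]:
        return {
            "background": self.n_background,
            "ub_only": self.n_ub_only,
            "shared": self.n_shared,
            "nedd8_only": self.n_nedd8_only,
            "bead_binder": self.n_bead_binder,
        }


_CLASS_GROUPS = {
    "background": (),
    "ub_only": ("Ub", "pUb", "nhpUb"),
    "nedd8_only": ("NEDD8", "pNEDD8", "nhpNEDD8"),
    "shared": ("Ub", "pUb", "nhpUb", "NEDD8", "pNEDD8", "nhpNEDD8"),
    "bead_binder": ("beads",),
}


def expected_dropout_rate(truth: AEMSTruth, log2_intensities: np.ndarray) -> float:
    """Mean of the logistic missingness model over the given cells."""
    z = (truth.dropout_midpoint - log2_intensities) / truth.dropout_scale
    return float(np.mean(1.0 / (1.0 + np.exp(-z))))


def make_aems_matrix(
    truth: AEMSTruth = AEMSTruth(),
    seed: int | None = None,
    groups: list[str] = DEFAULT_GROUPS,
) -> tuple[IntensityMatrix, pd.Series]:
    """Raw-scale intensity matrix plus per-protein true class labels.

    Log2 intensities are Gaussian around a per-protein base level with
    class-specific group enrichment; dropout is logistic in the true
    log2 intensity; decoy (reverse) and contaminant rows carry flags
    and ordinary background intensities.  Returned values are on the
    raw (2**log2) scale with missing cells as NaN, i.e. exactly what
    :func:`phosphoubl.enrichment.preprocess` expects.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    ids: list[str] = []
    counter = 0
    for cls, size in truth.class_sizes.items():
        for _ in range(size):
            counter += 1
            ids.append(f"P{counter:04d}")
            labels.append(cls)
    for i in range(truth.n_reverse):
        ids.append(f"REV__P{i + 1:04d}")
        labels.append("reverse")
    for i in range(truth.n_contaminant):
        ids.append(f"CON__P{i + 1:04d}")
        labels.append("contaminant")

    columns = pd.MultiIndex.from_tuples(
        [(g, r + 1) for g in groups for r in range(truth.replicates)],
        names=["group", "replicate"],
    )
    n_rows, n_cols = len(ids), len(columns)
    base = rng.normal(truth.base_mean, truth.base_sd, size=n_rows)
    log2 = np.tile(base[:, None], (1, n_cols))
    col_groups = np.array([c[0] for c in columns])
    for i, cls in enumerate(labels):
        enriched = _CLASS_GROUPS.get(cls, ())
        if enriched:
            log2[i, np.isin(col_groups, enriched)] += truth.effect
    if truth.replicate_sd > 0:
        log2 = log2 + rng.normal(0.0, truth.replicate_sd, size=log2.shape)
    values = np.power(2.0, log2)
    if truth.dropout:
        z = (truth.dropout_midpoint - log2) / truth.dropout_scale
        p_miss = 1.0 / (1.0 + np.exp(-z))
        values[rng.random(log2.shape) < p_miss] = np.nan
    frame = pd.DataFrame(values, index=pd.Index(ids, name="protein"), columns=columns)
    flags = pd.DataFrame(
        {
            "is_reverse": [lab == "reverse" for lab in labels],
            "is_contaminant": [lab == "contaminant" for lab in labels],
        },
        index=frame.index,
    )
    matrix = IntensityMatrix(values=frame, flags=flags, control_group="beads")
    return matrix, pd.Series(labels, index=frame.index, name="true_class")


# --------------------------------------------------------------------------
# targeted peptide table


@dataclass(frozen=True)
class TargetedTruth:
    """Ground truth for the targeted pS65 quantification generator.

    The default pS65 fractions give a 1.5-fold elevation under
    mitochondrial-stress conditions relative to mock treatment, on a
    low absolute phospho-stoichiometry.
    """

    fractions: tuple[tuple[str, float], ...] = (("DMSO", 0.02), ("CCCP", 0.03))
    noise_cv: float = 0.10
    #: technical replicates per biological replicate (study design:
    #: duplicates for the first two, triplicates for the rest)
    tech_replicates: tuple[int, ...] = (2, 2, 3, 3, 3)
    baseline_peptides: tuple[str, ...] = ("TLTGK", "EIEIDIEPTDK", "EGIPPQQQR")
    site_peptide: str = "ILGGSVLHLVLALR"  # NEDD8 61-74, spans S65
    baseline_area: float = 2e7
    site_area: float = 1e6

    @property
    def fold(self) -> float:
        d = dict(self.fractions)
        return d["CCCP"] / d["DMSO"]


def make_targeted_table(
    truth: TargetedTruth = TargetedTruth(), seed: int | None = None
) -> pd.DataFrame:
    """Peptide peak-area table for the targeted pS65 pipeline."""
    rng = np.random.default_rng(seed)
    rows = []
    for condition, fraction in truth.fractions:
        for bio, n_tech in enumerate(truth.tech_replicates, start=1):
            for tech in range(1, n_tech + 1):
                for pep in truth.baseline_peptides:
                    rows.append(
                        {
                            "peptide": pep,
                            "is_s65_site": False,
                            "phosphorylated": False,
                            "condition": condition,
                            "bio_replicate": bio,
                            "tech_replicate": tech,
                            "area": truth.baseline_area
                            * float(_lognormal_factor(rng, 0.3, ())),
                        }
                    )
                total = truth.site_area * float(_lognormal_factor(rng, 0.3, ()))
                for phospho, frac in ((False, 1.0 - fraction), (True, fraction)):
                    rows.append(
                        {
                            "peptide": truth.site_peptide,
                            "is_s65_site": True,
                            "phosphorylated": phospho,
                            "condition": condition,
                            "bio_replicate": bio,
                            "tech_replicate": tech,
                            "area": total
                            * frac
                            * float(_lognormal_factor(rng, truth.noise_cv, ())),
                        }
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# combined ground truth


@dataclass
class GroundTruth:
    """Serializable bundle of all generator parameters for one run."""

    scenario: str
    seed: int
    aems: AEMSTruth = field(default_factory=AEMSTruth)
    targeted: TargetedTruth = field(default_factory=TargetedTruth)

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "nmr": asdict(SCENARIOS[self.scenario]),
            "aems": asdict(self.aems),
            "targeted": asdict(self.targeted),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        aems = AEMSTruth(**payload["aems"])
        raw_t = dict(payload["targeted"])
        raw_t["fractions"] = tuple((c, f) for c, f in raw_t["fractions"])
        raw_t["tech_replicates"] = tuple(raw_t["tech_replicates"])
        raw_t["baseline_peptides"] = tuple(raw_t["baseline_peptides"])
        targeted = TargetedTruth(**raw_t)
        return cls(
            scenario=payload["scenario"],
            seed=payload["seed"],
            aems=aems,
            targeted=targeted,
        )
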