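"""Assigned 1H-15N cross-peak lists: domain types and file I/O.

A peak list holds, for one spectrum, the assigned backbone-amide
cross-peaks of a protein.  For slow-exchanging phosphorylated species a
residue can contribute two peaks, one per conformational state: the
relaxed state ``m`` (near-native) and the retracted state ``n``
(C-terminal beta5-strand slipped toward the core).  Spectra of
unphosphorylated species carry ``single``-state peaks; peaks that cannot
be ascribed to one state unambiguously are labelled ``ambiguous``.

The on-disk dialect is a UTF-8 tab-separated table with ``#`` comment
lines, fixed header ``residue_index  aa  state  shift_h  shift_n
height``, and optional ``# key: value`` metadata comments.  No published
peak-list standard carries conformational-state labels, so the package
defines this one.  A read-only subset of NMR-STAR v3 chemical-shift
loops is also supported so deposited assignments (e.g. BMRB entries for
NEDD8/pNEDD8) can be pulled in for cross-checks; deposited shift lists
carry no peak heights, so those peaks get height 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError, ValidationError
from .sequences import AA20

__all__ = [
    "State",
    "ResidueId",
    "Peak",
    "PeakList",
    "read_peaklist",
    "write_peaklist",
    "write_nmrstar_shifts",
    "parse_residue_token",
]


class State(str, Enum):
    """Conformational-state label of a cross-peak."""

    RELAXED = "m"
    RETRACTED = "n"
    SINGLE = "single"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True, order=True)
class ResidueId:
    """1-based residue number plus one-letter amino-acid code."""

    index: int
    aa: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AA20:
            raise ValidationError(f"unknown amino-acid code {self.aa!r}")

    def __str__(self) -> str:  # e.g. "L2"
        return f"{self.aa}{self.index}"


def parse_residue_token(token: str) -> ResidueId:
    """Parse a one-letter-code token like ``'L2'`` into a ResidueId."""
    aa, num = token[0], token[1:]
    if not num.isdigit():
        raise ValidationError(f"cannot parse residue token {token!r}")
    return ResidueId(int(num), aa)


@dataclass(frozen=True)
class Peak:
    """One assigned cross-peak: residue, state, shifts (ppm) and height."""

    residue: ResidueId
    state: State
    shift_h: float
    shift_n: float
    height: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_n)):
            raise ValidationError(f"non-finite chemical shift for {self.residue}")
        if not (math.isfinite(self.height) and self.height >= 0):
            raise ValidationError(f"height must be finite and >= 0 for {self.residue}")


@dataclass
class PeakList:
    """All assigned peaks of one spectrum.

    Invariants: at most one peak per (residue index, state) and all
    residue indices within ``sequence_length``.
    """

    protein: str = ""
    spectrum: str = ""
    conditions: dict = field(default_factory=dict)
    peaks: list[Peak] = field(default_factory=list)
    sequence_length: int = 76

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[int, State]] = set()
        for p in self.peaks:
            key = (p.residue.index, p.state)
            if key in seen:
                raise ValidationError(
                    f"duplicate peak for residue {p.residue} state {p.state.value!r}"
                )
            seen.add(key)
            if p.residue.index > self.sequence_length:
                raise ValidationError(
                    f"residue index {p.residue.index} exceeds sequence length "
                    f"{self.sequence_length}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def select(self, state: State | str) -> dict[int, Peak]:
        """Peaks of one state, keyed by residue index."""
        state = State(state)
        return {p.residue.index: p for p in self.peaks if p.state is state}

    def residues(self) -> set[int]:
        return {p.residue.index for p in self.peaks}


_HEADER = ["residue_index", "aa", "state", "shift_h", "shift_n", "height"]
_META_KEYS = ("protein", "spectrum", "ph", "temperature_K", "field_MHz")


def read_peaklist(path: str | Path, format: str = "tsv") -> PeakList:
    """Read a peak list from ``path``.

    ``format='tsv'`` reads the package's tab-separated dialect;
    ``format='nmrstar_shifts'`` reads the chemical-shift loop of an
    NMR-STAR v3 file (one single-state peak per residue with both H and
    N shifts, height 1).
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "nmrstar_shifts":
        return _read_nmrstar(path)
    raise ParseError(f"unknown peak-list format {format!r}")


def _read_tsv(path: Path) -> PeakList:
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != _HEADER:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {_HEADER}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != len(_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_HEADER)} columns, got {len(fields)}"
                )
            try:
                index = int(fields[0])
                sh, sn, ht = float(fields[3]), float(fields[4]), float(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            try:
                state = State(fields[2].strip())
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unknown state token {fields[2]!r}"
                ) from exc
            try:
                peak = Peak(
                    residue=ResidueId(index, fields[1].strip()),
                    state=state,
                    shift_h=sh,
                    shift_n=sn,
                    height=ht,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    if not header_seen:
        raise ParseError(f"{path}: missing header line")
    conditions = {
        k: float(meta[k]) for k in ("ph", "temperature_K", "field_MHz") if k in meta
    }
    length = int(meta.get("sequence_length", 76))
    return PeakList(
        protein=meta.get("protein", ""),
        spectrum=meta.get("spectrum", ""),
        conditions=conditions,
        peaks=peaks,
        sequence_length=length,
    )


def write_peaklist(pl: PeakList, path: str | Path) -> Path:
    """Write ``pl`` in the TSV dialect; round-trips field-for-field."""
    path = Path(path)
    lines = []
    if pl.protein:
        lines.append(f"# protein: {pl.protein}")
    if pl.spectrum:
        lines.append(f"# spectrum: {pl.spectrum}")
    if pl.sequence_length != 76:
        lines.append(f"# sequence_length: {pl.sequence_length}")
    for key, val in pl.conditions.items():
        lines.append(f"# {key}: {val!r}" if isinstance(val, str) else f"# {key}: {val}")
    lines.append("\t".join(_HEADER))
    for p in sorted(pl.peaks, key=lambda p: (p.residue.index, p.state.value)):
        lines.append(
            "\t".join(
                [
                    str(p.residue.index),
                    p.residue.aa,
                    p.state.value,
                    format(p.shift_h, ".8g"),
                    format(p.shift_n, ".8g"),
                    format(p.height, ".8g"),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# --- minimal NMR-STAR v3 chemical-shift loop support -----------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _star_tokens(text: str) -> Iterable[str]:
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield from line.split()


def _read_nmrstar(path: Path) -> PeakList:
    """Parse the ``_Atom_chem_shift`` loop of an NMR-STAR v3 file.

    Only the sequence code, residue type, atom id (H/N) and shift value
    columns are consumed; every residue with both an H and an N row
    becomes one single-state peak with height 1.
    """
    text = path.read_text(encoding="utf-8")
    tokens = list(_star_tokens(text))
    # locate a loop_ whose tags include _Atom_chem_shift.*
    i = 0
    loop_tags: list[str] = []
    loop_start = None
    while i < len(tokens):
        if tokens[i] == "loop_":
            tags = []
            j = i + 1
            while j < len(tokens) and tokens[j].startswith("_"):
                tags.append(tokens[j])
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                loop_tags = tags
                loop_start = j
                break
            i = j
        else:
            i += 1
    if loop_start is None:
        raise ParseError(f"{path}: no _Atom_chem_shift loop found")

    def col(name: str) -> int:
        for k, t in enumerate(loop_tags):
            if t == f"_Atom_chem_shift.{name}":
                return k
        raise ParseError(f"{path}: chemical-shift loop lacks tag {name}")

    c_seq = col("Seq_ID")
    c_comp = col("Comp_ID")
    c_atom = col("Atom_ID")
    c_val = col("Val")
    ncol = len(loop_tags)
    rows = []
    j = loop_start
    while j + ncol <= len(tokens) and tokens[j] != "stop_":
        rows.append(tokens[j : j + ncol])
        j += ncol
    shifts: dict[int, dict[str, float]] = {}
    aa_by_index: dict[int, str] = {}
    for row in rows:
        atom = row[c_atom]
        if atom not in ("H", "N"):
            continue
        idx = int(row[c_seq])
        comp = row[c_comp].upper()
        aa = _THREE_TO_ONE.get(comp, comp if len(comp) == 1 else None)
        if aa is None:
            raise ParseError(f"{path}: unknown residue type {row[c_comp]!r}")
        aa_by_index[idx] = aa
        shifts.setdefault(idx, {})[atom] = float(row[c_val])
    peaks = [
        Peak(
            residue=ResidueId(idx, aa_by_index[idx]),
            state=State.SINGLE,
            shift_h=hv["H"],
            shift_n=hv["N"],
            height=1.0,
        )
        for idx, hv in sorted(shifts.items())
        if "H" in hv and "N" in hv
    ]
    return PeakList(protein="", spectrum=path.stem, peaks=peaks)


def write_nmrstar_shifts(pl: PeakList, path: str | Path, entry_id: str = "entry") -> Path:
    """Write the H/N shifts of ``pl`` as a minimal NMR-STAR shift loop.

    Intended for round-trip tests and for exporting assignments in a
    form other NMR software can ingest; heights are not representable in
    the deposition format and are dropped.
    """
    path = Path(path)
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    lines = [
        f"data_{entry_id}",
        "",
        "save_assigned_chemical_shifts",
        "loop_",
        "  _Atom_chem_shift.ID",
        "  _Atom_chem_shift.Seq_ID",
        "  _Atom_chem_shift.Comp_ID",
        "  _Atom_chem_shift.Atom_ID",
        "  _Atom_chem_shift.Val",
    ]
    n = 0
    for p in sorted(pl.peaks, key=lambda p: p.residue.index):
        comp = one_to_three[p.residue.aa]
        for atom, val in (("H", p.shift_h), ("N", p.shift_n)):
            n += 1
            lines.append(f"  {n} {p.residue.index} {comp} {atom} {format(val, '.8g')}")
    lines += ["stop_", "save_", ""]
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
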