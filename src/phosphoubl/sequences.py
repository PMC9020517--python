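"""Mature 76-residue chains of human ubiquitin and NEDD8.

Residue numbering throughout the package is 1-based on these mature
chains (expression tags are cleaved in the constructs this package
models).  Backbone-amide observability: residue 1 has a free alpha-amine
rather than an amide, and prolines lack an amide proton, so neither
appears in a 1H-15N correlation spectrum.
"""

from __future__ import annotations

UBIQUITIN = "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
NEDD8 = "MLIKVKTLTGKEIEIDIEPTDKVERIKERVEEKEGIPPQQQRLIYSGKQMNDEKTAADYKILGGSVLHLVLALRGG"

SEQUENCES: dict[str, str] = {"ubiquitin": UBIQUITIN, "nedd8": NEDD8}

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def amide_observable_residues(sequence: str) -> list[int]:
    """1-based indices of residues with an observable backbone amide."""
    return [i for i, aa in enumerate(sequence, start=1) if i > 1 and aa != "P"]
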