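"""Genotype call coding shared across the package.

Calls are coded relative to each variant's own (major, minor) allele pair:
``AA`` = major-allele homozygote, ``AB`` = heterozygote, ``BB`` =
minor-allele homozygote, ``XX`` = missing.  Internally calls are stored as
int8 codes 0..3 in that order; ``XX`` deliberately sorts last so that the
called genotypes form the contiguous block 0..2.
"""

from __future__ import annotations

import numpy as np

AA: int = 0
AB: int = 1
BB: int = 2
XX: int = 3

CALL_LABELS: tuple[str, ...] = ("AA", "AB", "BB", "XX")
CODE_OF: dict[str, int] = {lab: i for i, lab in enumerate(CALL_LABELS)}

#: minor-allele copies carried by each called genotype code
DOSAGE_OF_CALL: tuple[float, ...] = (0.0, 1.0, 2.0)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}


def encode_calls(labels) -> np.ndarray:
    """Map an iterable/array of 'AA'/'AB'/'BB'/'XX' strings to int8 codes."""
    arr = np.asarray(labels, dtype=object)
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in, flat_out = arr.ravel(), out.ravel()
    for i, lab in enumerate(flat_in):
        try:
            flat_out[i] = CODE_OF[lab]
        except KeyError:
            raise ValueError(f"invalid genotype call {lab!r}") from None
    return out


def decode_calls(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_calls` (object array of labels)."""
    codes = np.asarray(codes)
    return np.array(CALL_LABELS, dtype=object)[codes]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G sites, where strand cannot be resolved."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})
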