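import numpy as np
import pandas as pd
import pytest

from gtconcord import GenotypeMatrix, HarmonizedPair
from gtconcord.calls import CALL_LABELS, CODE_OF, encode_calls


def make_matrix(calls, samples=None, alleles=None, chrom="1", pos_start=100):
    """Build a GenotypeMatrix from {rs_id: [call labels]}.

    ``alleles`` maps rs_id -> (major, minor); default ('A', 'G').
    """
    rs_ids = list(calls)
    n_samples = len(next(iter(calls.values())))
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    alleles = alleles or {}
    variants = pd.DataFrame({
        "rs_id": rs_ids,
        "chrom": chrom,
        "pos": np.arange(pos_start, pos_start + len(rs_ids)),
        "allele_major": [alleles.get(rs, ("A", "G"))[0] for rs in rs_ids],
        "allele_minor": [alleles.get(rs, ("A", "G"))[1] for rs in rs_ids],
    })
    grid = encode_calls([calls[rs] for rs in rs_ids])
    return GenotypeMatrix(variants, samples, grid)


def make_pair(seq_calls, micro_calls, **kwargs):
    """HarmonizedPair from two {rs_id: [labels]} dicts (same layout)."""
    seq = make_matrix(seq_calls, **kwargs)
    micro = make_matrix(micro_calls, **kwargs)
    orientation = pd.Series("identical", index=seq.rs_ids, name="orientation")
    return HarmonizedPair(seq=seq, micro=micro, orientation=orientation)


def random_pair(rng, n_snps=5, n_samples=5):
    """Random small pair over all four call categories."""
    labels = np.array(CALL_LABELS, dtype=object)
    seq = {f"rs{i}": list(labels[rng.integers(0, 4, n_samples)])
           for i in range(n_snps)}
    micro = {f"rs{i}": list(labels[rng.integers(0, 4, n_samples)])
             for i in range(n_snps)}
    return make_pair(seq, micro)


# ---------------------------------------------------------------------
# brute-force oracles (independent of the vectorised implementation)
# ---------------------------------------------------------------------

def brute_crossclass(pair):
    """Count the 16 cells with explicit python loops over label strings."""
    counts = {(a, b): 0 for a in CALL_LABELS for b in CALL_LABELS}
    seq_df, micro_df = pair.seq.to_frame(), pair.micro.to_frame()
    for rs in pair.rs_ids:
        for s in pair.samples:
            counts[(seq_df.loc[rs, s], micro_df.loc[rs, s])] += 1
    out = np.zeros((4, 4), dtype=np.int64)
    for (a, b), c in counts.items():
        out[CODE_OF[a], CODE_OF[b]] = c
    return out


def brute_conditional_rates(pair, rs):
    """Per-SNP conditional 4x4 for one SNP, by explicit counting."""
    seq_df, micro_df = pair.seq.to_frame(), pair.micro.to_frame()
    rates = np.full((4, 4), np.nan)
    for j, micro_lab in enumerate(CALL_LABELS):
        cols = [s for s in pair.samples if micro_df.loc[rs, s] == micro_lab]
        if not cols:
            continue
        for i, seq_lab in enumerate(CALL_LABELS):
            rates[i, j] = sum(seq_df.loc[rs, s] == seq_lab
                              for s in cols) / len(cols)
    return rates


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
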