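"""Published summary data shipped with the package.

The GAW18 genotype data itself is access-restricted, but the pooled
cross-classification of its 240,456 dual-platform SNPs over 959
individuals was published in full, and every headline discordance
proportion of that study is recomputable from the pooled table alone.
The counts below reproduce that published table (rows = sequence call,
columns = microarray call, order AA, AB, BB, XX) and serve as a
real-data worked example and regression anchor for the pooled-table
statistics.
"""

from __future__ import annotations

import numpy as np

from gtconcord.concordance import CrossClassTable

#: SNPs matched between the two platforms by rs number before allele checks
GAW18_N_MATCHED_SNPS = 297_197
#: matched SNPs excluded because the two platforms reported different
#: allele pairs at the site
GAW18_N_ALLELE_MISMATCH_SNPS = 56_741
#: samples with calls on both platforms
GAW18_N_SAMPLES = 959
#: directly sequenced / imputed split of those samples
GAW18_N_NGS = 464
GAW18_N_IMPUTED = 495

_GAW18_COUNTS = np.array([
    # micro:      AA          AB          BB       XX
    [117_284_236,     58_271,      1_309,   2_554],   # seq AA
    [    101_015, 65_584_521,     29_302,   8_970],   # seq AB
    [      6_844,    339_856, 41_656_995,  24_361],   # seq BB
    [  3_009_304,  1_506_621,    977_234,   5_911],   # seq XX
], dtype=np.int64)


def gaw18_pooled_crossclass() -> CrossClassTable:
    """Pooled 4x4 cross-classification of the GAW18 dual-platform calls.

    240,456 SNPs x 959 individuals = 230,597,304 call pairs summed over
    all SNPs and samples; sequence-platform calls on the rows,
    microarray calls on the columns.
    """
    n_snps = GAW18_N_MATCHED_SNPS - GAW18_N_ALLELE_MISMATCH_SNPS
    return CrossClassTable(_GAW18_COUNTS.copy(), n_snps=n_snps,
                           n_samples=GAW18_N_SAMPLES)
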