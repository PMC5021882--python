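"""Extract the four descriptor groups for one synthetic protein.

Builds a random sequence, a secondary-structure string, a PSSM and a
domain-hit table, runs each extractor, and prints the dimensions plus a
few leading values of each feature vector.
"""

from profold import (
    extract_aascpp_features,
    extract_dssp_features,
    extract_fund_features,
    extract_pssm_features,
    gen_domain_universe,
    gen_dssp_fixture,
    gen_hits_fixture,
    gen_pssm_fixture,
    gen_sequence,
)

record = gen_sequence(150, seed=7, record_id="demo")
dssp, _ = gen_dssp_fixture(150, seed=7)
pssm, _ = gen_pssm_fixture(150, seed=7)
universe = gen_domain_universe(500)
hits, _ = gen_hits_fixture(universe, 20, seed=7)

for fv in (
    extract_dssp_features(dssp),
    extract_aascpp_features(record.sequence),
    extract_pssm_features(pssm),
    extract_fund_features(hits, universe),
):
    head = ", ".join(f"{n}={v:.3f}" for n, v in zip(fv.column_names[:3], fv.values[:3]))
    print(f"{fv.group_name:>6}: {len(fv)}D  [{head}, ...]")

# The DSSP vector is 40D secondary-structure statistics, AAsCPP is 20D
# amino-acid composition plus 8 x 21D physicochemical CTD blocks (188D),
# PSSM is the 20 column means of the log-odds profile, and FunD is a binary
# occupancy vector over the 500-domain universe (1 where a hit's E-value
# is at most 0.001).
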