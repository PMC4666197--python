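"""Extract CDR3 clonotypes from error-free CDR3-centered reads.

Positive-control reads place the CDR3 midpoint at the read midpoint; at
101 nt nearly every CDR3 fits and the extractor at its default 12/12
minimum V/J alignment recovers the truth exactly.
"""

import numpy as np

from tcrseek import (
    ExtractionParams,
    JunctionModel,
    centered_reads,
    clean_reads,
    extract_cdr3,
    generate_fixture_germline,
    simulate_repertoire,
)

ref = generate_fixture_germline(10, 2, 6, "beta", seed=1)
repertoire = simulate_repertoire(
    ref, "beta", 300, JunctionModel.default(), np.random.default_rng(2)
)
reads = clean_reads(centered_reads(repertoire, 101))
table = extract_cdr3(reads, ref, ExtractionParams(min_v_align=12, min_j_align=12))

truth = {t.cdr3_nt for t in repertoire}
called = table.cdr3_nt_set("beta")
print(f"{len(reads)} reads -> {len(table.df)} clonotypes "
      f"({table.total_reads} CDR3-bearing reads)")
print(f"recovered {len(called & truth)} of {len(truth)} distinct truth CDR3s; "
      f"false calls: {len(called - truth)}")
# Error-free 101-nt reads leave generous V/J flanks, so recovery is complete
# and nothing outside the truth set is called.
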