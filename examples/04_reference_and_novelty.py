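"""Compare a CNV map against reference SV panels: frequency matching,
false-positive removal, novelty calling, frequency correlation."""

import numpy as np

from cnvmap import frequency_correlation
from cnvmap.intervals import GenomicInterval
from cnvmap.io import ReferenceSVSet
from cnvmap.mapbuild import MapLocus, attach_reference_matches, drop_false_positives, find_novel

rng = np.random.default_rng(1)

# a toy map of 40 deletion loci with known population frequencies
loci = []
for i in range(40):
    start = 1_000_000 + i * 100_000
    loci.append(
        MapLocus(
            id=f"CNVR_1_{i + 1}",
            interval=GenomicInterval(1, start, start + int(rng.integers(2_000, 50_000))),
            map_type="DEL",
            states_present=frozenset({1}),
            frequency_pct=float(np.round(rng.uniform(1, 80), 2)),
        )
    )

# a reference panel covering 30 of them, with allele frequencies that track
# the map frequencies up to noise; the other 10 loci are absent -> novel
records = []
for m in loci[:30]:
    af = min(1.0, max(0.0, m.frequency_pct / 100 + rng.normal(0, 0.03)))
    records.append((m.interval, [af]))
panel = ReferenceSVSet("reference_panel", records)

loci = attach_reference_matches(loci, [panel])
loci = drop_false_positives(loci, [panel])
novel = find_novel(loci, [panel])
print(f"map loci: {len(loci)}, matched in panel: "
      f"{sum(bool(m.ref_matches) for m in loci)}, novel: {len(novel)}")

pairs = [(m.frequency_pct / 100, m.ref_matches["reference_panel"])
         for m in loci if m.ref_matches]
r, (lo, hi), p = frequency_correlation(pairs)
print(f"frequency correlation vs panel: r={r:.2f} (95% CI [{lo:.2f}, {hi:.2f}], p={p:.1e})")
# High r says the cohort's allele frequencies agree with the panel's; the
# 10 unmatched loci share no 50% of their length with any record, so they
# are flagged novel.
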