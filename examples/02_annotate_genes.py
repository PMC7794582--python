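"""Label how a CNV disrupts a transcript and filter to functional events.

Span labels use the transcript's own orientation: "txStart-Intron1" means
the event runs from upstream of the transcription start into intron 1,
wherever that lies genomically.
"""

from cnvmap import GenomicInterval, enrichment_test, functional_filter, overlap_genes
from cnvmap.io import GeneModel

gene = GeneModel(
    "NM_000100", "DEMO", "+",
    tx=GenomicInterval(9, 136_125_000, 136_150_000),
    exons=(
        GenomicInterval(9, 136_125_000, 136_126_000),
        GenomicInterval(9, 136_130_000, 136_131_000),
        GenomicInterval(9, 136_140_000, 136_141_000),
        GenomicInterval(9, 136_149_000, 136_150_000),
    ),
)

events = {
    "exonic deletion": (GenomicInterval(9, 136_129_500, 136_131_500), "DEL"),
    "intronic deletion": (GenomicInterval(9, 136_132_000, 136_139_000), "DEL"),
    "whole-gene duplication": (GenomicInterval(9, 136_120_000, 136_155_000), "DUP"),
    "straddling duplication": (GenomicInterval(9, 136_140_500, 136_155_000), "DUP"),
}

for name, (locus, ltype) in events.items():
    overlaps = overlap_genes(name, locus, [gene], mode="any")
    kept = functional_filter(
        overlaps, {name: ltype}, {name: locus}, {gene.gene_id: gene}
    )
    span = overlaps[0].span_label if overlaps else "-"
    verdict = "kept (functional)" if kept else "discarded"
    print(f"{name:26s} span={span:18s} -> {verdict}")

# Gene-set fold enrichment: 5 of 10 query genes in a 20-gene set drawn
# from a 1000-gene background gives fold (5/10)/(20/1000) = 25.
background = {f"g{i}" for i in range(1000)}
res = enrichment_test(
    query_genes={f"g{i}" for i in range(10)},
    gene_set={f"g{i}" for i in range(5)} | {f"g{i}" for i in range(100, 115)},
    background=background,
    set_name="demo pathway",
)
print(f"\nenrichment: k={res.k}/m={res.m} vs K={res.K}/N={res.N} "
      f"fold={res.fold:.1f} p={res.p:.2e}")
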