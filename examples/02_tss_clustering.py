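"""Cluster TSS-seq tags into transcription start site regions.

Tags within 20 bp (same strand) chain into clusters; clusters within 400 bp
chain into TSS regions; regions under 20 supporting tags are discarded.
"""

from lncprobe.tss import TssTag, cluster_tags, group_clusters

# 22 tags around position 1000 in two nearby bursts, plus a lone distant tag
tags = (
    [TssTag("chr1", 1000 + i, "+") for i in range(12)]
    + [TssTag("chr1", 1300, "+")] * 10
    + [TssTag("chr1", 9000, "+")]
)

clusters = cluster_tags(tags, cluster_gap=20)
print("clusters (start, end, tags):")
for c in clusters:
    print(f"  {c.start:>6} {c.end:>6} {c.tag_count:>4}")

regions = group_clusters(clusters, group_gap=400, min_tags=20)
print("\nTSS regions after grouping and the 20-tag filter:")
for r in regions:
    print(f"  [{r.start}, {r.end})  tags={r.tag_count}  clusters={r.n_clusters}")

print("\nThe two bursts (12 + 10 tags, 289 bp apart) merge into one region of")
print("22 tags and survive; the lone tag at 9000 forms a region of 1 and is")
print("discarded by the < 20 tag rule.")
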