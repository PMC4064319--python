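"""Decompose a pre-miRNA hairpin into its functional substructures.

Builds a toy 80-nt precursor with a 5p and a 3p mature arm, splits it
into flank / rest-of-mature / seed / loop segments, and looks up the
region hit by a genomic position — the same operation the pipeline uses
to classify every cohort variant.
"""

from mirvarmap import GenomicInterval, MatureMiRNA, PreMiRNA, decompose

pre = PreMiRNA(
    id="toy-mir-1",
    interval=GenomicInterval("1", 1001, 1080, "+"),
    mature_arms=(
        MatureMiRNA("toy-miR-1-5p", GenomicInterval("1", 1005, 1026, "+"), arm="5p"),
        MatureMiRNA("toy-miR-1-3p", GenomicInterval("1", 1050, 1071, "+"), arm="3p"),
    ),
)

smap = decompose(pre)
print(f"{pre.id}: {pre.interval.length} nt, {len(smap.segments)} segments\n")
for seg in smap.segments:
    iv = seg.interval
    print(f"  {str(seg.label):<14} {iv.start}-{iv.end}  ({iv.length} nt)")

pos = 1007  # mature position 3 of the 5p arm
print(f"\nposition {pos} falls in: {smap.locate(pos)}")
print("(the seed is mature positions 2-8 - the target-recognition region;")
print(" a variant here is the kind the map flags as potentially functional)")
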