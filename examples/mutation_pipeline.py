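"""Somatic-mutation filtering on a toy cohort of variant records.

Five cells share a candidate site; the pipeline demands heterozygosity
in at least three cells, a deeply covered homozygous-reference normal
bulk, and presence in the tumor bulk.  The second scenario shows the
shallow-normal trap: the same site is dropped when the normal bulk has
fewer than 21 reads, because a germline SNP with dropout in a shallow
normal sample would masquerade as a somatic mutation.
"""

from snpanchor import GenomicSite, VariantRecord, call_mutations


def rec(gt, dp, pos=500):
    return VariantRecord(
        site=GenomicSite("chr7", pos, "G"), alt="A",
        qual=60.0, fs=2.0, qd=10.0, gq=80.0, dp=dp, gt=gt,
    )


cells = {f"cell{i}": [rec("0/1" if i < 3 else "0/0", dp=12)] for i in range(5)}
tumor = [rec("0/1", dp=40)]

for normal_depth in (35, 15):
    normal = [rec("0/0", dp=normal_depth)]
    found = call_mutations(cells, normal, tumor)
    status = (
        f"{len(found)} candidate(s): "
        + ", ".join(f"{c.site.chrom}:{c.site.pos} {c.site.ref}->{c.alt} "
                    f"in {len(c.supporting_cells)} cells" for c in found)
        if found else "no candidates"
    )
    print(f"normal bulk depth {normal_depth:2d} -> {status}")

print()
print("With 35 normal reads the site is a credible somatic mutation (het in")
print("3 cells, absent from a reliable normal); with 15 reads the normal")
print("genotype cannot be trusted, so the site is excluded, not called.")
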