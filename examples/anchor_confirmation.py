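"""The central strategy: confirming wild-types with linked SNP anchors.

Simulates single cells with regional allele dropout, then contrasts two
quantities measured against the known truth:

* the naive false-negative rate — how often a true heterozygote is NOT
  recovered in a cell, which equals the dropout rate; and
* the error rate of anchor-confirmed wild-type (-1) calls, where absence
  of the mutant allele only counts when a germline het SNP within 90 bp
  shows BOTH of its alleles, proving the region kept both haplotypes.
"""

from snpanchor.benchmarks import (
    anchor_confirmation_experiment,
    fnr_recovery_experiment,
)

ADO = 0.25  # regional dropout rate (platforms span roughly 0.07-0.44)

fnr = fnr_recovery_experiment(seed=42, ado_rate=ADO)
print(f"configured regional dropout rate : {ADO:.3f}")
print(f"naive per-site FNR (estimated)   : {fnr['average_fnr']:.4f}"
      f"  over {fnr['n_evaluable']} evaluable het sites")

conf = anchor_confirmation_experiment(seed=42, ado_rate=ADO)
print(f"anchor-confirmed wild-type calls : {conf['n_confirmed_wildtype']}")
print(f"confirmed calls that were wrong  : {conf['n_errors']}")
print(f"confirmation error rate          : {conf['error_rate']:.2g}")

print()
print("Without anchoring, one in four heterozygous sites is silently lost")
print("to dropout; with an anchor SNP sharing the amplification segment,")
print("a confirmed wild-type is essentially never a hidden mutant.")
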