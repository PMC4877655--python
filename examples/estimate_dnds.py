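"""Per-locus dN/dS under purifying selection.

Simulates a 10-sequence codon alignment evolved at omega = 0.2 and estimates
the mean pairwise omega with a codon-column bootstrap 95% CI, the same
summary the pipeline reports per receptor locus.
"""

from ladderlens import locus_mean_dnds, pairwise_dnds, simulate_codon_family

records, truth = simulate_codon_family(n_seqs=10, n_codons=300, omega=0.2,
                                       t=0.3, seed=5)
summary = locus_mean_dnds(records, n_boot=1000, seed=5, locus="TLR_demo")

est = pairwise_dnds(records[0], records[1])
print(f"example pair: dN = {est.dn:.4f}, dS = {est.ds:.4f}, "
      f"omega = {est.omega:.3f}")
print(f"locus {summary.locus}: mean omega = {summary.mean_omega:.3f} "
      f"(95% CI {summary.ci_low:.3f}-{summary.ci_high:.3f}, "
      f"{summary.n_pairs} pairs)")

# omega well below 1 with a CI excluding 1 indicates purifying selection;
# the estimate brackets the true simulated value of 0.2.
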