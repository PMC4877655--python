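"""Scan LRR modules and classify ectodomain architectures.

Simulates one ectodomain per architecture (single-domain, three-domain,
trans-three-domain), detects its LRR modules from the concave-surface motif,
and classifies it from the hydrogen-bond competence of the ladder residues.
"""

from ladderlens import classify_architecture, detect_lrr_modules, simulate_ectodomain
from ladderlens.ladder import ladder_competence

for arch in ("SD", "TD", "TTD"):
    record, truth = simulate_ectodomain(arch, n_modules=21, seed=42)
    ann = detect_lrr_modules(record.sequence, record_id=record.id)
    flags = [ladder_competence(r) for r in ann.ladder_residues]
    call = classify_architecture(flags)
    print(f"{record.id}: {ann.n_modules} LRR modules, "
          f"ladder {ann.ladder_residues}, verdict {call.verdict}")
    for seg in call.segments:
        print(f"  {seg.name:<11} modules {seg.modules[0]:>2}-{seg.modules[1]:<2} "
              f"incompetent {seg.incompetent_fraction:.0%} "
              f"(longest run {seg.longest_incompetent_run}) "
          f"{'BROKEN' if seg.broken else 'intact'}")

# The verdict follows the ladder: an intact ladder across all three
# subdomains is SD, a central break is TD, breaks in both termini are TTD.
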