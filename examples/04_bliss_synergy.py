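"""Bliss-independence synergy scoring from confluency time courses.

Builds control / single-drug / combination growth curves, computes each
treatment's effect E = 1 - treated/control at the endpoint, and scores
the combination against the Bliss independence surface.
"""

from enhancerhub.pheno import bliss_score, effect
from enhancerhub.synthetic import SimConfig, generate_confluency

cfg = SimConfig(seed=2)  # single-drug effects 0.4 and 0.3

for offset, label in [(0.0, "independent"), (0.12, "synergistic")]:
    curves = generate_confluency(cfg, synergy_offset=offset)
    e_a = effect(curves["drug_a"], curves["control"])
    e_b = effect(curves["drug_b"], curves["control"])
    e_combo = effect(curves["combo"], curves["control"])
    score = bliss_score(e_combo, e_a, e_b)
    print(
        f"{label:>12}: E_a = {e_a.E:.2f}, E_b = {e_b.E:.2f}, "
        f"E_combo = {e_combo.E:.2f} -> Bliss score = {score:+.3f}"
    )

print(f"\nworked example: E_a = E_b = 0.5, E_combo = 0.9 -> "
      f"Bliss score = {bliss_score(0.9, 0.5, 0.5):+.2f}")

# A score of 0 means the combination does exactly what independent drugs
# would (E_a + E_b - E_a*E_b); positive values quantify synergy beyond it.
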