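"""End-to-end screening on synthetic data.

Builds a seeded Italian-like lexicon, assembles the 255-item battery from
it, simulates a grade-5 reader who migrates letters on half of the
migratable items (the letter-position-dyslexia signature), codes and scores
the responses, and diagnoses the profile against the packaged norms.
"""

from lettura import (
    CodingResources,
    ReaderProfile,
    assemble_battery,
    code_battery,
    flag_profile,
    load_embedded_norms,
    score_child,
    simulate_reader,
    synth_lexicon,
)
from lettura.io import format_report_text, profile_report

lexicon = synth_lexicon(seed=1, size=1200)
battery = assemble_battery(lexicon, seed=1)
print(f"lexicon: {len(lexicon)} words; battery: {len(battery.items)} items")

profile = ReaderProfile(child_id="demo-lpd", grade=5, theta_migration=0.5)
records = simulate_reader(profile, battery, seed=42)
resources = CodingResources(lexicon=lexicon, semantic_table=battery.semantic_table)
coded = code_battery(battery.items, records, resources)
errors = [c for c in coded if not c.is_correct]
print(f"simulated reader made errors on {len(errors)} of {len(coded)} items")

score = score_child(coded, battery.items, grade=5)
norms = load_embedded_norms()
diagnosis = flag_profile(score, norms)
print(format_report_text(profile_report(diagnosis, score, norms)))
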