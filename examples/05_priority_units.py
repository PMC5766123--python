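"""Conservation-priority scoring of populations.

Categorises haplotypes by network position and distribution (ancestral /
derived / endemic / rare / common), then scores every population with
H = Ha + Hd + He + Hr + Hc + 10*pi_i/pi and flags priority protection
units (H > 10).  Also scores the published component table, whose hand
assignments differ from the strict rules in a few cells.
"""

from haplogeo import bretschneidera
from haplogeo.genealogy import mj_network
from haplogeo.priority import categorize, rank_priority, scores_from_components

dataset = bretschneidera.load_dataset()
net = mj_network(dataset.matrix, dataset.global_counts())

assignment = categorize(dataset, net)
for cat in ("ancestral", "endemic", "rare", "common"):
    print(f"{cat:>10}: {sorted(assignment.of(cat))}")

scores, flagged = rank_priority(dataset, assignment)
print("\nrule-derived scores (top 8):")
for s in scores[:8]:
    star = "*" if s.priority else " "
    print(f" {star} {s.population:<4} Ha={s.Ha:<4.0f} Hd={s.Hd:<4.0f} He={s.He:<4.0f}"
          f" Hr={s.Hr:<4.0f} Hc={s.Hc:<4.0f} 10pi_i/pi={s.pi_ratio:4.2f}  H={s.H:5.2f}")
print(f"  rule-derived priority units: {sorted(flagged)}")

pub_scores, pub_flagged = scores_from_components(
    bretschneidera.load_priority_components())
print(f"\npublished-component priority units: {sorted(pub_flagged)}")
print("  " + ", ".join(f"{s.population}={s.H:g}" for s in pub_scores[:7]))
print("\nPopulations carrying ancestral, endemic or rare haplotypes (and the")
print("diverse HZ/CY stands) rank as priority protection units.")
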