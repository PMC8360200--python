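"""Score candidates against the seed reductases: homologs pass, decoys fail.

A divergent homolog keeps alignable similarity to its parent seed; a
shuffled decoy has the same composition but no order, so the local
alignment and profile scores both collapse.
"""

from sdrmine.search import build_profile, score_orf
from sdrmine.synthetic import SEED_PROTEINS, default_templates, mutate_protein, shuffle_decoy

profile = build_profile(SEED_PROTEINS)
templates = default_templates()

print(f"profile: {profile.consensus_len} columns, max window score "
      f"{profile.max_score:.0f} bits\n")
print(f"{'candidate':28s} {'norm':>6s} {'profile':>8s}  passed")
for target in (30.0, 40.0, 60.0, 90.0):
    mut = mutate_protein(templates[0], target, seed=int(target))
    hit = score_orf((f"homolog_{target:.0f}pct", mut), SEED_PROTEINS, profile)
    print(f"{hit.orf_id:28s} {hit.normalized_score:6.3f} {hit.profile_score:8.1f}  {hit.passed}")
for s in range(3):
    decoy = shuffle_decoy(templates[s], seed=s)
    hit = score_orf((f"shuffled_decoy_{s}", decoy), SEED_PROTEINS, profile)
    print(f"{hit.orf_id:28s} {hit.normalized_score:6.3f} {hit.profile_score:8.1f}  {hit.passed}")

print("\nnorm = local-alignment score / self-score of the best seed (1.0 = the"
      "\nseed itself); the default pass threshold of 0.06 sits well above the"
      "\nshuffle null (~0.03) and below the weakest real homolog (~0.09).")
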