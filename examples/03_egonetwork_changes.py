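"""Egonetwork changes: which regions rewire with learning?

The learning-minus-control difference matrix Delta gives each region a row
describing how its local neighborhood changed; the row norm is the
amplitude of the change and row-wise cosine similarity across the social
and asocial conditions asks whether the *direction* of rewiring is shared.
"""

from fosnet import (
    amplitude_null,
    amplitudes,
    build_tower,
    consensus_network,
    cosine_null,
    difference_matrix,
    generate_activation,
    study_like_spec,
)

table, _ = generate_activation(study_like_spec(seed=3))
nets = {t: consensus_network(build_tower(table, t), 0.05) for t in
        ("SL", "SC", "AL", "AC")}

dm_s = difference_matrix(nets["SL"], nets["SC"], condition="S")
dm_a = difference_matrix(nets["AL"], nets["AC"], condition="A")

amp = amplitudes(dm_s)
null = amplitude_null(dm_s, n_reps=5000, seed=0)
large = [nid for nid, f in zip(dm_s.node_ids, null.large) if f]
print(f"social condition: amplitude band [{null.band_low:.2f}, {null.band_high:.2f}], "
      f"{len(large)} region(s) above it: {large[:6]}")
# Regions above the resampling band rewired more than a random reshuffling
# of the same connectivity changes would produce.

cn = cosine_null(dm_s, dm_a, n_reps=1000, seed=1)
similar = [nid for nid, f in zip(cn.node_ids, cn.similar) if f]
print(f"{len(similar)} region(s) rewire in significantly similar directions "
      f"in the two conditions (z > 1.5, p < 0.05): {similar[:6]}")
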