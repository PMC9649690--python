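"""Score lineage specificity on a synthetic pan-cancer expression atlas.

Generates a TPM atlas with 200 planted lineage-specific transcripts
(home-lineage share 0.8 over 22 lineages), scores every transcript with
S_t = log2(N) - Shannon entropy of its lineage expression ratios, and
applies the calling rule (top ratio > 2x second, score > 1).
"""

import numpy as np

import txaxes as tx

atlas, truth = tx.simulate_expression_atlas(tx.AtlasSimConfig(seed=1))
profile = tx.aggregate_by_lineage(atlas)
called = tx.call_lineage_specific(tx.specificity_scores(profile))

planted = set(truth.specific_transcripts)
hits = set(called.index[called["is_specific"]]) & planted

print(f"transcripts scored:          {len(called)}")
print(f"max possible score log2(22): {np.log2(22):.3f}")
print(f"lineage-specific calls:      {int(called['is_specific'].sum())}")
print(f"planted transcripts found:   {len(hits)}/{len(planted)} "
      f"(recall {len(hits)/len(planted):.2f})")
example = sorted(hits)[0]
row = called.loc[example]
print(f"example: {example} score={row['score']:.2f} "
      f"called={row['called_lineage']} (planted: "
      f"{truth.specific_transcripts[example]})")
# A recall near 1 means the entropy score + 2x-ratio rule recovers the
# transcripts whose expression was concentrated in one lineage by design.
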