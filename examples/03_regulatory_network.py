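"""Build a high-confidence RBP-transcript network from synthetic evidence.

Simulates per-RBP knockdown DE tables and binding peaks with planted
regulated transcripts, then keeps an edge only when the transcript passes
|fold change| > 1.5 & FDR < 0.05 AND carries at least one exonic binding
peak of that RBP.
"""

import txaxes as tx

tids = [f"T{i:03d}" for i in range(100)]
models = tx.make_transcript_models(tids, seed=0)
cfg = tx.RegulomeSimConfig(n_rbps=6, n_regulated_per_rbp=25,
                           frac_bound_of_regulated=0.7, seed=0)
de_set, peaks, truth = tx.simulate_regulome(tids, cfg, models)

edges = tx.build_network(de_set, peaks, models)
summary = tx.summarize_network(edges)

planted = {
    (rbp, t)
    for rbp, pairs in truth.regulated.items()
    for t, _ in pairs
    if t in set(truth.bound[rbp])
}
recovered = set(zip(edges["rbp_id"], edges["transcript_id"]))
print(f"edges recovered: {len(recovered)} (planted regulated-and-bound: "
      f"{len(planted)}, overlap {len(recovered & planted)})")
print("\nper-RBP regulated transcript counts (total = up + down):")
print(summary["per_rbp"].to_string(index=False))
top = summary["per_transcript"].sort_values("n_rbps", ascending=False).head(3)
print("\nmost co-regulated transcripts:")
print(top.to_string(index=False))
# The double evidence filter recovers exactly the planted pairs: knockdown
# response alone (or binding alone) never creates an edge.
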