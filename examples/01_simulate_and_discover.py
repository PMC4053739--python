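"""Plant a degenerate motif in synthetic data and rediscover it.

Generates 150 genes on a periodic expression trajectory, plants the 6-mer
pair WGCGCA = {AGCGCA, TGCGCA} in one region of expression space, then runs
the full pipeline: q-mer seeding with shuffle FDR, greedy refinement,
redundancy filtering.
"""

import motifdens as md

X = md.gen_expression(150, 12, "periodic", noise_sd=0.3, seed=1)
plant = md.PlantSpec(md.IUPACMotif("WGCGCA"), p_inside=0.9, p_outside=0.02,
                     focal_fraction=0.25)
records, truth = md.gen_sequences(X, bg_at_fraction=0.6, length=150,
                                  plants=[plant], seed=2)
print(f"planted {len(truth.plants)} occurrences in "
      f"{len(truth.inside_genes['WGCGCA'])} focal genes")

cfg = md.Config(q=6, k=25, seed=3, max_len=8)
res = md.run_discovery(X, records, cfg)

print(f"{len(res.seeds)} seed(s) passed FDR < {cfg.seed_fdr}:")
for m, score, fdr in res.seeds:
    print(f"  {m}  score={score:.4f}  fdr={fdr:.4f}")
print("filtered motifs (score = mutual information in bits):")
for r in res.motifs:
    print(f"  {r.motif}  score={r.score:.4f}  from seed {r.seed}  n_m={r.n_m}")
# The refined motif covers both planted words (possibly via the reverse
# strand: a motif and its reverse complement are the same object here).
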