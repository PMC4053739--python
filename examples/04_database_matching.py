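"""Evaluate predicted motifs against a PWM database.

Predictions are converted to PWMs (each IUPAC symbol becomes the uniform
distribution over its nucleotide set) and aligned to database motifs by
summed per-column Pearson correlation.  P values come from column-shuffled
databases; matches are counted at a global 15% FDR (Benjamini-Hochberg),
and two predictions hitting the same database motif count once.
"""

import numpy as np

import motifdens as md
from motifdens.dbmatch import PWM, benchmark_matches, iupac_to_pwm

rng = np.random.default_rng(7)
# a database of 25 random motifs plus two real ones
database = [PWM(f"random{i}", rng.dirichlet(np.ones(4), size=8))
            for i in range(25)]
database += [iupac_to_pwm(md.IUPACMotif("WAGACAAT"), "factor_A"),
             iupac_to_pwm(md.IUPACMotif("CACGTGSS"), "factor_B")]

# three predictions: two variants of factor_A's site and one of factor_B's
queries = [iupac_to_pwm(md.IUPACMotif("WAGACAA"), "pred1"),
           iupac_to_pwm(md.IUPACMotif("AGACAAT"), "pred2"),
           iupac_to_pwm(md.IUPACMotif("CACGTGS"), "pred3")]

count, table = benchmark_matches(queries, database, fdr=0.15,
                                 n_shuffles=300, seed=0)
print(table[["query", "target", "score", "p_value", "bh_significant",
             "counted"]].to_string(index=False))
print(f"counted matches: {count}")
# pred1 and pred2 both best-match factor_A, so only the lower-P one counts:
# redundancy among predictions earns no credit.
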