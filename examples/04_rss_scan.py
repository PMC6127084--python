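"""Scan deletion-breakpoint sequences for cryptic RSS motifs.

Scores every heptamer-spacer-nonamer placement with the package's
weighted matrix on one sequence with a planted consensus RSS and one
random sequence, then summarises the best scores against the reference
threshold used to judge RAG involvement.
"""

from talclone.rss import default_matrix, find_fixed_motifs, scan_rss, summarize_breakpoint_rss
from talclone.simdata import make_breakpoint_sequences

mat = default_matrix()
planted = make_breakpoint_sequences(1, 120, embed="consensus_rss", spacer=23, seed=6)[0]
random_ = make_breakpoint_sequences(1, 120, embed="none", seed=7)[0]

best = {}
for rec in (planted, random_):
    hit = scan_rss(rec.seq, sequence_id=rec.id, matrix=mat)["global_best"]
    best[rec.id] = hit
    print(f"{rec.id} ({rec.embed}): best total {hit.total:.2f} "
          f"(heptamer {hit.heptamer_score:.2f} + nonamer {hit.nonamer_score:.2f} "
          f"+ spacer {hit.spacer_penalty:.2f}) at {hit.heptamer_start} on {hit.strand}")

caca = find_fixed_motifs(planted.seq, motifs=("CACA",))
print(f"CACA tetramer occurrences in the planted sequence: {len(caca)}")

summary = summarize_breakpoint_rss(best, threshold=8.55)
print(f"max score {summary.max_score:.2f} vs threshold {summary.threshold}: "
      f"{summary.classification}")
print()
print("A planted consensus RSS reaches the matrix maximum (9.5); random")
print("sequence stays well below the 8.55 reference, the score level seen")
print("at genuinely RAG-driven breakpoints.")
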