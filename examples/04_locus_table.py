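"""Summarize per-sample insertion findings into a locus-by-sample table.

Loads the packaged worked-example table of non-reference PERV-LTR loci
surveyed in three Vietnamese native pig genomes (VnP1-VnP3), merges loci
observed across samples (within 500 bp), and partitions rows by whether the
locus was confirmed with both TSD copies or a single one.  Each cell holds
what that sample's data supported at the locus: a solo LTR, a full provirus
of a given type (PERV-A/B/C), or no LTR evidence.
"""

import nrltr as N
from nrltr.evaluate import load_vnp_locus_table, summarize_loci

per_sample, raw = load_vnp_locus_table()
table = summarize_loci(per_sample)

print(f"{table.n_both_tsd} loci confirmed with both 5'- and 3'-TSD, "
      f"{table.n_single_tsd} with a single TSD "
      f"({table.n_both_tsd + table.n_single_tsd} total)\n")

frame = table.to_frame()
print(frame.head(8).to_string(index=False))
print("...")
counts = frame[frame.section == "both_tsd"][["VnP1", "VnP2", "VnP3"]]
print("\nstatus counts over both-TSD loci:")
print(counts.apply(lambda col: col.value_counts()).fillna(0).astype(int))
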