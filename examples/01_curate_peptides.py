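"""Curate a small peptide collection: length, residue and redundancy filters.

Writes a toy FASTA, runs the full curation pipeline (length <= 50, the 20
proteinogenic residues only, greedy 80%-identity deduplication) and prints
the report.  The identity measure is matched alignment columns over the
shorter sequence, so "AAAAAAAAAA" vs "AAAAAAAAAC" (90%) collapses at the
80% threshold while unrelated sequences survive.
"""

import tempfile
from pathlib import Path

from cppmine import curate, read_fasta

FASTA = """\
>tat GRKKRRQRRRPPQ
GRKKRRQRRRPPQ
>penetratin
RQIKIWFQNRRMKWKK
>penetratin_copy
RQIKIWFQNRRMKWKK
>near_duplicate
AAAAAAAAAA
>near_duplicate_2
AAAAAAAAAC
>too_long
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV
>non_natural
ACDXBZEF
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "peptides.fasta"
    path.write_text(FASTA)
    dataset = read_fasta(path)

curated, report = curate(dataset, max_len=50, identity_threshold=0.80)

print(f"input records:        {report.n_input}")
print(f"removed (length>50):  {report.n_removed_length}")
print(f"removed (non-natural):{report.n_removed_nonnatural}")
print(f"removed (redundant):  {report.n_removed_redundant}")
print(f"kept:                 {report.n_output}")
for p in curated:
    print(f"  {p.id:16s} {p.sequence}")
# The survivors are the unique, valid, mutually dissimilar peptides the
# classifier would actually be trained on.
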