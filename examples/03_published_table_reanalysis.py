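"""Re-derive frequencies and activity calls from the published read counts.

The bundled reference table holds the eleven candidate repeat pairs of the
S. miltiorrhiza mitogenome (MN585275.1/MN585276.1) with their published
per-conformation PacBio read counts.  This script recomputes the
recombination frequency of every row and applies the default activity
thresholds; exactly the nine PCR-validated repeats should come out active
(r10 is excluded by its 5,835 bp span, r11 by minor-read support).
"""

import mitorecomb as mr
from mitorecomb import reference

records = mr.call_active_repeats(reference.reference_records())
print("repeat  length  type      Mac1 Mac2 Mic1 Mic2   freq%  active")
for rec in records:
    c = rec.counts
    freq = mr.recombination_frequency(c)
    print(
        f"{rec.repeat.id:6s}  {rec.repeat.aln_length:6d}  "
        f"{rec.repeat.orientation:8s}  {c.mac1:4d} {c.mac2:4d} "
        f"{c.mic1:4d} {c.mic2:4d}  {freq:6.2f}  {'yes' if rec.active else 'no'}"
    )
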