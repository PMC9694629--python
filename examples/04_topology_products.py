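"""Predict the circular products of recombination at each validated repeat.

Using the published repeat coordinates on the two chromosomes (MC1 328,915
bp, MC2 85,199 bp), applies one reciprocal exchange per repeat and reports
the product circles: the inter-molecular repeat r01 fuses the two
chromosomes into one 414,114 bp circle, direct intra-molecular repeats
split MC1 in two, and inverted ones invert the intervening segment without
changing the molecule count.
"""

import mitorecomb as mr
from mitorecomb import reference

genome = mr.Genome.from_sequences(
    {"MC1": "A" * reference.MC1_LENGTH, "MC2": "A" * reference.MC2_LENGTH}
)

for rep in reference.reference_repeats():
    if rep.id not in reference.VALIDATED_ACTIVE:
        continue
    mols = mr.genome_to_molecules(genome, [rep])
    mic = mr.recombine(mols, rep.id)
    lengths = ", ".join(f"{m.length:,} bp" for m in mic.molecules)
    kind = (
        "fusion" if rep.inter_molecular
        else ("inversion" if rep.orientation == "inverted" else "split")
    )
    print(f"{rep.id} ({rep.orientation:8s}, {kind:9s}) -> "
          f"{len(mic.molecules)} circle(s): {lengths}")
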