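"""Derive frameshift protein nomenclature from coding indels.

A toy CDS loses one base: the reading frame shifts at codon 3 and a premature
stop appears one codon later, written p.L3SfsX2. The same arithmetic, run in
reverse on the published notation p.L471LfsX56 (a retained-anchor 14-bp
deletion), places that premature termination codon at residue 527.
"""

import warnings

from hrscreen.variants import (
    CodingSequence,
    apply_indel,
    describe_frameshift,
    parse_coding_variant,
    stop_position_from_fs,
    translate_to_stop,
)

cds = CodingSequence("toy", "ATGAAACTCTTAGGGTAA")
ref, _ = translate_to_stop(cds.sequence)
variant = parse_coding_variant("c.7_7del")
mutant = apply_indel(cds, variant)
alt, _ = translate_to_stop(mutant)
print(f"reference CDS : {cds.sequence}  ->  {ref}")
print(f"after c.7_7del: {mutant}   ->  {alt}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    consequence = describe_frameshift(ref, alt)
    print(f"consequence   : {consequence.notation} "
          f"(stop at residue {consequence.stop_position})")

    stop = stop_position_from_fs("p.L471LfsX56")
print(f"\np.L471LfsX56 -> premature stop at residue {stop}")
print("With a retained anchor the stop sits at anchor + offset: 471 + 56 = 527.")
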