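"""Filter AP-MS identifications down to specific interactors.

Two filters: a protein counts in an experiment only with >= 3 peptides scoring
strictly above a MASCOT ions score of 20, and proteins seen in more than 15%
of 193 independent control immunoprecipitations are common background
(bait proteins are exempt).
"""

from hrscreen.proteomics import (
    BackgroundRegistry,
    IdentificationRecord,
    confident_hits,
    filter_common_background,
)

records = [
    IdentificationRecord("BAIT1", "ip1", [60, 55, 48, 31], bait=True),
    IdentificationRecord("PARTNER_A", "ip1", [25, 31, 22]),
    IdentificationRecord("WEAK_ID", "ip1", [20, 25, 30]),     # 20 is not above 20
    IdentificationRecord("HSP_STICKY", "ip1", [44, 39, 27, 24]),
]
confident = confident_hits(records)
print("confident identifications:", sorted(p for p, _ in confident))

registry = BackgroundRegistry(
    {"BAIT1": 2, "PARTNER_A": 5, "HSP_STICKY": 29}, n_control_ips=193
)
retained, excluded, _ = filter_common_background(
    sorted(p for p, _ in confident), registry, baits=["BAIT1"]
)
print("retained after background filter:", retained)
print("excluded as common background  :", excluded)
print()
print("WEAK_ID fails the 3-peptide rule; HSP_STICKY appears in 29/193 (15.03%)")
print("control pull-downs — just over the 15% line — and is excluded, while a")
print("protein at 28/193 (14.5%) would survive.")
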