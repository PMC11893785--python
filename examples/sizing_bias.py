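"""Amplicon vs PCR-free WGS sizing bias from the reported medians.

Long-range-PCR amplification contracts long GAA tracts slightly; the two
individuals sized by both assays show the amplicon-based medians running
11-14 units short of the PCR-free WGS medians.
"""

from fgf14repeat import sizing_bias

lrpcr = {"msa_patient": 269, "ataxia_patient": 307}
wgs = {"msa_patient": 283, "ataxia_patient": 318}

records, summary = sizing_bias(lrpcr, wgs)
for record in records:
    print(
        f"{record.sample_id}: LR-PCR {record.lrpcr_median_units} units, "
        f"WGS {record.wgs_median_units} units, "
        f"difference {record.difference:+.0f} units"
    )
print(f"underestimate range: {summary['min_difference']:.0f}"
      f"-{summary['max_difference']:.0f} units")
# Positive differences mean the amplicon assay underestimates the repeat:
# a caller should flag amplicon sizes near the 250-unit pathogenic cutoff.
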