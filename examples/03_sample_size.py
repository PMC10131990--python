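"""Sample-size calculations for an RDS survey and the capture rounds.

Both use n = deff * z^2 * p(1-p) / w^2 inflated for nonresponse/loss.
"""

from crc3s import DesignSpec, crc_capture_sample_size, rds_sample_size
from crc3s.datasets import rwanda_design_specs

for name, spec in rwanda_design_specs().items():
    print(f"{name}: RDS n = {rds_sample_size(spec)} (p = {spec.p:.3f})")
# e.g. Kigali needs 1027 RDS participants for +/-2.5 points of absolute
# precision on an 11.3% prevalence with design effect 1.5 and 10% nonresponse.

capture = DesignSpec(p=0.003, w=0.005, deff=1.5, z=1.96, adjust=0.15)
print("capture round (0.3% prevalence, 15% coupon loss):", crc_capture_sample_size(capture))
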