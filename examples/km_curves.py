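"""Kaplan-Meier curves per arm for the three conventional endpoints.

LRC = time to loco-regional relapse, PFS = time to progression,
OS = time to death/last follow-up, all in days from registration.
"""

from gapsurv import SyntheticParams, generate_cohort, km_by_arm

cohort, _ = generate_cohort(SyntheticParams(censor_rate=0.2, seed=3))

for endpoint in ("lrc", "pfs", "os"):
    curves = km_by_arm(cohort, endpoint)
    at_365 = {arm: round(c.survival_at(365.0), 3) for arm, c in curves.items()}
    print(f"{endpoint.upper()}: S(365 d) per arm = {at_365}")
# The printed values are the product-limit probabilities of still being
# event-free at one year; PFS sits between LRC (earlier event) and OS.
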