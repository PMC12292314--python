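"""Printed reference-cohort statistics used as frozen expectations.

These are the published per-node means/SDs and per-case V_sum scores of the
30-case reference cohort, transcribed independently of the packaged CSV so
the tests check the pipeline's recomputation against print.
"""

import numpy as np

PRINTED_MEANS = np.array([6.85, 6.41, 5.94, 4.82, 3.72, 3.77, 6.10, 5.62, 5.50])
PRINTED_SDS = np.array([2.78, 2.88, 2.16, 2.27, 1.10, 1.71, 2.47, 2.29, 2.39])

# V_sum per case, cases 1..30 in table order
PRINTED_VSUM = np.array(
    [
        9.47, 13.59, 14.48, 8.98, 13.06, 13.12, 16.10, 15.84, 10.01, 15.42,
        11.15, 22.41, 17.73, 16.63, 22.20, 13.17, 17.88, 27.70, 25.39, 11.81,
        17.53, 11.82, 16.73, 18.15, 18.25, 11.94, 21.73, 19.92, 12.29, 7.90,
    ]
)
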