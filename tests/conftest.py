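"""Shared fixtures: published jetting measurements for a 250 µm microvalve nozzle.

The PRINTED_* tables are measured dimensionless values for six bioink
families reported for a 250 µm orifice, 1000 µs dwell, 200 Hz microvalve
system; they serve as input data for identity and classification checks.
"""

import pytest

# (We, Re, Oh) triples where all three values are reported precisely.
PRINTED_TRIPLES = {
    "fibrinogen 5 mg/mL": (105.39, 1191.5, 0.0086),
    "fibrinogen 20 mg/mL": (95.97, 773.0, 0.0127),
    "collagen_I 1 mg/mL": (23.813, 95.011, 0.051),
    "collagen_I 7 mg/mL": (0.895, 0.163, 5.806),
    "matrigel 0.1%": (65.573, 637.390, 0.0127),
    "matrigel 10%": (9.310, 14.836, 0.2057),
    "alginate 0.05%": (65.708, 871.11, 0.0093),
    "alginate 0.5%": (16.452, 57.812, 0.0702),
    "agarose 0.1%": (57.46, 510.0, 0.0149),
}

# (Oh, Re, ~K_splash) — splash parameter values reported to ~1 significant figure.
PRINTED_SPLASH = {
    "fibrinogen 5 mg/mL": (0.0086, 1191.5, 60.0),
    "fibrinogen 20 mg/mL": (0.0127, 773.0, 52.0),
    "collagen_I 1 mg/mL": (0.051, 95.011, 15.0),
    "collagen_I 7 mg/mL": (5.806, 0.163, 0.6),
    "matrigel 0.1%": (0.0127, 637.390, 41.0),
    "matrigel 10%": (0.2057, 14.836, 6.0),
    "alginate 0.05%": (0.0093, 871.11, 44.0),
    "alginate 0.5%": (0.0702, 57.812, 11.0),
}

# Froude numbers printed alongside (We, Re) for property inversion.
PRINTED_FROUDE = {
    "fibrinogen 5 mg/mL": 96.278,
    "collagen_I 1 mg/mL": 62.389,
    "collagen_I 7 mg/mL": 26.713,
    "matrigel 0.1%": 86.199,
    "matrigel 10%": 48.116,
    "alginate 0.05%": 91.147,
    "alginate 0.5%": 58.347,
}

NOZZLE_DIAMETER_M = 250e-6


@pytest.fixture
def printed_triples():
    return PRINTED_TRIPLES


@pytest.fixture
def printed_splash():
    return PRINTED_SPLASH
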