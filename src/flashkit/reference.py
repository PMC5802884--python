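"""Published summary statistics of the restrained-firefly light-exposure study.

The original raw spectrometer recordings were never deposited; what
survives in print is the per-wavelength group summary of flash intensity
and flash frequency at the two stimulus levels, together with the dark
base values and the two intensity-frequency correlation coefficients.
These ship with the package so the summary-level results can be
recomputed without external data, and so the simulator has a realistic
default behavioral profile.
"""

from __future__ import annotations

import io

import pandas as pd

#: Dark-baseline group means (initial 1-min dark recordings, six males).
BASE_INTENSITY = 5420.0  # counts
BASE_RATE = 43.167  # peaks/min

#: Published Pearson correlations between per-wavelength mean flash
#: intensity and mean flash frequency.
DIM_CORRELATION = -0.9655009
BRIGHT_CORRELATION = -0.8027756

#: Published exposure-order likelihood-ratio statistics (flash frequency).
ORDER_CHISQ_DIM = 15.205
ORDER_CHISQ_BRIGHT = 14.668

#: Fraction of males that ceased signaling under bright short/mid-wavelength
#: light (three of six).
CESSATION_FRACTION = 0.5

#: Wavelengths (nm) at or below which ambient light altered signaling.
RESPONSIVE_MAX_NM = 533

_TABLE = """\
wavelength\tlevel\tmean_intensity\tsd_intensity\tdoc_intensity\tp_intensity\tmean_rate\tsd_rate\tdoc_rate\tp_rate
444\tdim\t11420\t4498\t2.106\t0.0021\t22.67\t15.65\t0.525\t0.0042
463\tdim\t11330\t4615\t2.090\t0.010\t23.78\t15.02\t0.551\t0.0049
488\tdim\t11380\t4605\t2.099\t0.018\t17.78\t10.91\t0.412\t0.000014
515\tdim\t9879\t3540\t1.823\t0.021\t24.44\t12.81\t0.566\t0.0098
533\tdim\t8584\t3125\t1.584\t0.066\t32.44\t13.93\t0.752\t0.046
597\tdim\t5639\t4912\t1.040\t0.94\t44.89\t6.504\t1.040\t0.30
628\tdim\t6605\t2848\t1.219\t0.91\t42.67\t17.28\t0.988\t0.55
663\tdim\t6881\t3381\t1.269\t0.72\t46.22\t16.67\t1.071\t0.43
444\tbright\t11719\t5489\t2.162\t0.23\t14.44\t14.80\t0.335\t0.0019
463\tbright\t9259\t2854\t1.708\t0.19\t12.67\t11.29\t0.293\t0.00042
488\tbright\t10606\t4595\t1.957\t0.13\t8.222\t7.78\t0.190\t0.000014
515\tbright\t6594\t3388\t1.217\t0.59\t14.89\t12.29\t0.345\t0.0018
533\tbright\t10462\t4941\t1.930\t0.051\t27.11\t15.70\t0.628\t0.032
597\tbright\t4688\t2615\t0.865\t0.48\t56.44\t11.38\t1.308\t0.92
628\tbright\t6381\t3407\t1.177\t0.97\t45.78\t15.61\t1.060\t0.56
663\tbright\t4968\t3351\t0.917\t0.98\t54.00\t22.45\t1.251\t0.87
"""


def reference_effect_table() -> pd.DataFrame:
    """Return the published per-(wavelength, level) summary as a DataFrame.

    Columns: wavelength (nm), level ({dim, bright}), mean/sd of flash
    intensity (counts) and flash rate (peaks/min), the printed
    degree-of-change ratios (``doc_*`` = group mean / dark base value) and
    the printed mixed-model p-values.
    """
    df = pd.read_csv(io.StringIO(_TABLE), sep="\t")
    df["wavelength"] = df["wavelength"].astype(int)
    return df
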