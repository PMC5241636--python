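"""Published benchmark tables of the Wuji pill compatibility study.

The original study reports whole-curve LOOCV errors (value +- SD across the
nine time points) for every (learner, chaining mode, compound) cell, and
improvement percentages of MT over ST and over RMT derived from them via

    imp = (err_ref - err_MT) / err_ref * 100.

The real concentration measurements are not public, so these printed tables
are the only quantitative reference for the study; they are embedded here to
let the improvement arithmetic be recomputed and checked.  ``EXACT_CELLS``
freezes the improvement cells that recompute from the error tables to the
printed two decimals; the remaining cells were evidently rounded before the
division (two are outright misprints) and differ in the last digits.
"""

from __future__ import annotations

import pandas as pd

from .evaluation import improvement

BASES = ("LR", "PR", "SVR", "ANN", "PLS")
MODES = ("ST", "MT", "RMT")
MEASURES = ("MAE", "MAPE", "RMSE")
COMPOUNDS = ("ber", "pal", "evo", "rut", "pae")

#: measure -> (base, mode) -> compound -> whole error (+- SD not included)

BENCHMARK_ERRORS = {
    'MAE': {
        ('LR', 'ST'): {"ber": 61.92, "pal": 35.9, "evo": 21.91, "rut": 12.34, "pae": 80.94},
        ('LR', 'MT'): {"ber": 55.54, "pal": 27.49, "evo": 10.39, "rut": 10.21, "pae": 47.04},
        ('LR', 'RMT'): {"ber": 51.2, "pal": 26.86, "evo": 20.65, "rut": 13.62, "pae": 84.09},
        ('PR', 'ST'): {"ber": 67.42, "pal": 35.05, "evo": 18.3, "rut": 14.89, "pae": 65.19},
        ('PR', 'MT'): {"ber": 57.79, "pal": 27.88, "evo": 18.18, "rut": 13.57, "pae": 53.23},
        ('PR', 'RMT'): {"ber": 61.78, "pal": 30.8, "evo": 19.57, "rut": 14.98, "pae": 70.73},
        ('SVR', 'ST'): {"ber": 62.23, "pal": 35.9, "evo": 20.62, "rut": 11.47, "pae": 74.47},
        ('SVR', 'MT'): {"ber": 50.36, "pal": 24.59, "evo": 10.18, "rut": 9.95, "pae": 44.6},
        ('SVR', 'RMT'): {"ber": 62.99, "pal": 33.11, "evo": 19.86, "rut": 12.04, "pae": 78.71},
        ('ANN', 'ST'): {"ber": 109.6, "pal": 59.84, "evo": 34.27, "rut": 18.01, "pae": 106.08},
        ('ANN', 'MT'): {"ber": 95.26, "pal": 47.53, "evo": 23.82, "rut": 17.86, "pae": 82.89},
        ('ANN', 'RMT'): {"ber": 88.68, "pal": 51.68, "evo": 30.28, "rut": 18.15, "pae": 110.23},
        ('PLS', 'ST'): {"ber": 64.97, "pal": 33.32, "evo": 21.39, "rut": 18.7, "pae": 66.24},
        ('PLS', 'MT'): {"ber": 63.09, "pal": 43.65, "evo": 64.38, "rut": 32.04, "pae": 73.38},
        ('PLS', 'RMT'): {"ber": 70.04, "pal": 33.9, "evo": 24.18, "rut": 22.02, "pae": 74.65},
    },
    'MAPE': {
        ('LR', 'ST'): {"ber": 0.464, "pal": 1.073, "evo": 1.95, "rut": 0.692, "pae": 0.878},
        ('LR', 'MT'): {"ber": 0.375, "pal": 0.752, "evo": 0.8, "rut": 0.491, "pae": 0.525},
        ('LR', 'RMT'): {"ber": 0.394, "pal": 0.895, "evo": 1.874, "rut": 0.75, "pae": 0.926},
        ('PR', 'ST'): {"ber": 0.511, "pal": 1.136, "evo": 1.383, "rut": 0.677, "pae": 0.651},
        ('PR', 'MT'): {"ber": 0.383, "pal": 0.89, "evo": 1.422, "rut": 0.633, "pae": 0.493},
        ('PR', 'RMT'): {"ber": 0.436, "pal": 0.983, "evo": 1.512, "rut": 0.694, "pae": 0.737},
        ('SVR', 'ST'): {"ber": 0.468, "pal": 0.947, "evo": 1.413, "rut": 0.54, "pae": 0.711},
        ('SVR', 'MT'): {"ber": 0.338, "pal": 0.574, "evo": 0.721, "rut": 0.426, "pae": 0.473},
        ('SVR', 'RMT'): {"ber": 0.493, "pal": 0.889, "evo": 1.302, "rut": 0.544, "pae": 0.82},
        ('ANN', 'ST'): {"ber": 0.872, "pal": 1.846, "evo": 3.62, "rut": 0.895, "pae": 1.286},
        ('ANN', 'MT'): {"ber": 0.654, "pal": 1.411, "evo": 2.265, "rut": 0.957, "pae": 1.068},
        ('ANN', 'RMT'): {"ber": 0.668, "pal": 1.594, "evo": 2.573, "rut": 1.063, "pae": 1.373},
        ('PLS', 'ST'): {"ber": 0.462, "pal": 1.035, "evo": 1.529, "rut": 0.89, "pae": 0.701},
        ('PLS', 'MT'): {"ber": 0.471, "pal": 1.507, "evo": 5.595, "rut": 1.602, "pae": 0.899},
        ('PLS', 'RMT'): {"ber": 0.523, "pal": 1.051, "evo": 1.769, "rut": 1.039, "pae": 0.775},
    },
    'RMSE': {
        ('LR', 'ST'): {"ber": 66.88, "pal": 37.46, "evo": 22.49, "rut": 13.08, "pae": 82.05},
        ('LR', 'MT'): {"ber": 60.92, "pal": 29.38, "evo": 11.07, "rut": 11.17, "pae": 48.61},
        ('LR', 'RMT'): {"ber": 55.52, "pal": 28.52, "evo": 21.43, "rut": 14.39, "pae": 85.85},
        ('PR', 'ST'): {"ber": 71.83, "pal": 36.63, "evo": 18.89, "rut": 15.58, "pae": 66.5},
        ('PR', 'MT'): {"ber": 63.03, "pal": 29.53, "evo": 18.78, "rut": 14.32, "pae": 54.68},
        ('PR', 'RMT'): {"ber": 66.71, "pal": 32.46, "evo": 20.36, "rut": 15.75, "pae": 72.1},
        ('SVR', 'ST'): {"ber": 67.09, "pal": 37.37, "evo": 21.18, "rut": 12.22, "pae": 75.79},
        ('SVR', 'MT'): {"ber": 55.72, "pal": 26.42, "evo": 10.83, "rut": 10.83, "pae": 45.96},
        ('SVR', 'RMT'): {"ber": 68.0, "pal": 34.98, "evo": 20.67, "rut": 12.81, "pae": 80.33},
        ('ANN', 'ST'): {"ber": 113.71, "pal": 61.09, "evo": 34.73, "rut": 18.8, "pae": 107.3},
        ('ANN', 'MT'): {"ber": 99.38, "pal": 49.43, "evo": 24.48, "rut": 18.89, "pae": 84.48},
        ('ANN', 'RMT'): {"ber": 92.62, "pal": 53.8, "evo": 31.19, "rut": 19.11, "pae": 113.69},
        ('PLS', 'ST'): {"ber": 69.61, "pal": 34.91, "evo": 22.02, "rut": 19.31, "pae": 67.66},
        ('PLS', 'MT'): {"ber": 68.47, "pal": 45.02, "evo": 64.8, "rut": 32.64, "pae": 74.72},
        ('PLS', 'RMT'): {"ber": 75.07, "pal": 35.62, "evo": 24.89, "rut": 22.65, "pae": 76.24},
    },
}

#: (measure, reference mode) -> base -> compound -> printed improvement (%)
PRINTED_IMPROVEMENTS = {
    ('RMSE', 'ST'): {
        'LR': {"ber": 8.91, "pal": 21.57, "evo": 50.76, "rut": 14.65, "pae": 40.76},
        'PR': {"ber": 12.25, "pal": 19.39, "evo": 0.56, "rut": 8.07, "pae": 17.78},
        'SVR': {"ber": 16.94, "pal": 29.3, "evo": 48.86, "rut": 11.36, "pae": 39.36},
        'ANN': {"ber": 12.6, "pal": 19.09, "evo": 29.53, "rut": -0.05, "pae": 21.27},
        'PLS': {"ber": 1.64, "pal": -28.98, "evo": -194.3, "rut": -69.01, "pae": -10.43},
    },
    ('RMSE', 'RMT'): {
        'LR': {"ber": -9.73, "pal": -3.02, "evo": 48.34, "rut": 22.38, "pae": 43.38},
        'PR': {"ber": 5.52, "pal": 9.03, "evo": 7.76, "rut": 9.08, "pae": 24.16},
        'SVR': {"ber": 18.06, "pal": 24.47, "evo": 47.61, "rut": 15.46, "pae": 42.79},
        'ANN': {"ber": -7.3, "pal": 8.12, "evo": 21.51, "rut": 1.15, "pae": 25.69},
        'PLS': {"ber": 8.79, "pal": -26.39, "evo": -160.35, "rut": -44.11, "pae": 1.99},
    },
    ('MAPE', 'ST'): {
        'LR': {"ber": 19.13, "pal": 29.89, "evo": 58.96, "rut": 29.11, "pae": 40.17},
        'PR': {"ber": 24.95, "pal": 2163, "evo": -2.8, "rut": 6.5, "pae": 24.2},
        'SVR': {"ber": 27.66, "pal": 39.37, "evo": 49.0, "rut": 21.1, "pae": 33.46},
        'ANN': {"ber": 24.97, "pal": 23.57, "evo": 37.41, "rut": -0.69, "pae": 16.93},
        'PLS': {"ber": -2.07, "pal": -45.56, "evo": -266.01, "rut": -80.01, "pae": -28.23},
    },
    ('MAPE', 'RMT'): {
        'LR': {"ber": 4.82, "pal": 15.98, "evo": 57.31, "rut": 34.53, "pae": 43.3},
        'PR': {"ber": 12.16, "pal": 9.46, "evo": 5.95, "rut": 8.79, "pae": 33.11},
        'SVR': {"ber": 31.44, "pal": 35.43, "evo": 44.62, "rut": 21.69, "pae": 42.32},
        'ANN': {"ber": 2.1, "pal": 11.48, "evo": 11.97, "rut": 9.97, "pae": 22.21},
        'PLS': {"ber": 9.94, "pal": -43.39, "evo": -216.28, "rut": -54.19, "pae": -16.0},
    },
    ('MAE', 'ST'): {
        'LR': {"ber": 10.31, "pal": 23.41, "evo": 52.55, "rut": 17.21, "pae": 41.89},
        'PR': {"ber": 14.3, "pal": 20.44, "evo": 0.62, "rut": 8.91, "pae": 18.35},
        'SVR': {"ber": 19.07, "pal": 31.5, "evo": 50.63, "rut": 13.27, "pae": 40.1},
        'ANN': {"ber": 13.08, "pal": 20.56, "evo": 30.48, "rut": 0.83, "pae": 21.87},
        'PLS': {"ber": 2.9, "pal": -31.02, "evo": -200.84, "rut": -71.31, "pae": -10.78},
    },
    ('MAE', 'RMT'): {
        'LR': {"ber": -8.48, "pal": -2.35, "evo": 49.69, "rut": 25.04, "pae": 44.06},
        'PR': {"ber": 6.46, "pal": 9.48, "evo": 7.1, "rut": 9.41, "pae": 24.74},
        'SVR': {"ber": 20.05, "pal": 25.73, "evo": 48.74, "rut": 17.36, "pae": 43.34},
        'ANN': {"ber": -7.42, "pal": 8.03, "evo": 21.33, "rut": 1.6, "pae": 24.8},
        'PLS': {"ber": 9.92, "pal": -28.76, "evo": -166.25, "rut": -45.5, "pae": 1.7},
    },
}

#: improvement cells that recompute exactly (+-0.01) from BENCHMARK_ERRORS
EXACT_CELLS = (
    ('RMSE', 'ST', 'LR', 'ber'),
    ('RMSE', 'ST', 'LR', 'pal'),
    ('RMSE', 'ST', 'LR', 'pae'),
    ('RMSE', 'ST', 'PR', 'ber'),
    ('RMSE', 'ST', 'PR', 'pal'),
    ('RMSE', 'ST', 'PR', 'pae'),
    ('RMSE', 'ST', 'SVR', 'ber'),
    ('RMSE', 'ST', 'SVR', 'pal'),
    ('RMSE', 'ST', 'SVR', 'evo'),
    ('RMSE', 'ST', 'SVR', 'pae'),
    ('RMSE', 'ST', 'ANN', 'ber'),
    ('RMSE', 'ST', 'ANN', 'pal'),
    ('RMSE', 'ST', 'ANN', 'pae'),
    ('RMSE', 'ST', 'PLS', 'ber'),
    ('RMSE', 'ST', 'PLS', 'pae'),
    ('RMSE', 'RMT', 'LR', 'ber'),
    ('RMSE', 'RMT', 'LR', 'pal'),
    ('RMSE', 'RMT', 'LR', 'evo'),
    ('RMSE', 'RMT', 'LR', 'rut'),
    ('RMSE', 'RMT', 'LR', 'pae'),
    ('RMSE', 'RMT', 'PR', 'ber'),
    ('RMSE', 'RMT', 'PR', 'pal'),
    ('RMSE', 'RMT', 'PR', 'evo'),
    ('RMSE', 'RMT', 'PR', 'rut'),
    ('RMSE', 'RMT', 'PR', 'pae'),
    ('RMSE', 'RMT', 'SVR', 'ber'),
    ('RMSE', 'RMT', 'SVR', 'pal'),
    ('RMSE', 'RMT', 'SVR', 'evo'),
    ('RMSE', 'RMT', 'SVR', 'rut'),
    ('RMSE', 'RMT', 'SVR', 'pae'),
    ('RMSE', 'RMT', 'ANN', 'ber'),
    ('RMSE', 'RMT', 'ANN', 'pal'),
    ('RMSE', 'RMT', 'ANN', 'evo'),
    ('RMSE', 'RMT', 'ANN', 'rut'),
    ('RMSE', 'RMT', 'ANN', 'pae'),
    ('RMSE', 'RMT', 'PLS', 'ber'),
    ('RMSE', 'RMT', 'PLS', 'pal'),
    ('RMSE', 'RMT', 'PLS', 'evo'),
    ('RMSE', 'RMT', 'PLS', 'rut'),
    ('RMSE', 'RMT', 'PLS', 'pae'),
    ('MAPE', 'ST', 'PR', 'rut'),
    ('MAPE', 'ST', 'ANN', 'pal'),
    ('MAPE', 'RMT', 'LR', 'ber'),
    ('MAPE', 'RMT', 'LR', 'pal'),
    ('MAPE', 'RMT', 'LR', 'evo'),
    ('MAPE', 'RMT', 'LR', 'rut'),
    ('MAPE', 'RMT', 'LR', 'pae'),
    ('MAPE', 'RMT', 'PR', 'ber'),
    ('MAPE', 'RMT', 'PR', 'pal'),
    ('MAPE', 'RMT', 'PR', 'evo'),
    ('MAPE', 'RMT', 'PR', 'rut'),
    ('MAPE', 'RMT', 'PR', 'pae'),
    ('MAPE', 'RMT', 'SVR', 'ber'),
    ('MAPE', 'RMT', 'SVR', 'pal'),
    ('MAPE', 'RMT', 'SVR', 'evo'),
    ('MAPE', 'RMT', 'SVR', 'rut'),
    ('MAPE', 'RMT', 'SVR', 'pae'),
    ('MAPE', 'RMT', 'ANN', 'ber'),
    ('MAPE', 'RMT', 'ANN', 'pal'),
    ('MAPE', 'RMT', 'ANN', 'evo'),
    ('MAPE', 'RMT', 'ANN', 'rut'),
    ('MAPE', 'RMT', 'ANN', 'pae'),
    ('MAPE', 'RMT', 'PLS', 'ber'),
    ('MAPE', 'RMT', 'PLS', 'pal'),
    ('MAPE', 'RMT', 'PLS', 'evo'),
    ('MAPE', 'RMT', 'PLS', 'rut'),
    ('MAPE', 'RMT', 'PLS', 'pae'),
    ('MAE', 'ST', 'LR', 'ber'),
    ('MAE', 'ST', 'LR', 'pae'),
    ('MAE', 'ST', 'PR', 'pae'),
    ('MAE', 'ST', 'SVR', 'ber'),
    ('MAE', 'ST', 'SVR', 'pal'),
    ('MAE', 'ST', 'SVR', 'evo'),
    ('MAE', 'ST', 'ANN', 'ber'),
    ('MAE', 'ST', 'ANN', 'rut'),
    ('MAE', 'ST', 'ANN', 'pae'),
    ('MAE', 'ST', 'PLS', 'ber'),
    ('MAE', 'ST', 'PLS', 'pae'),
    ('MAE', 'RMT', 'LR', 'ber'),
    ('MAE', 'RMT', 'LR', 'pal'),
    ('MAE', 'RMT', 'LR', 'evo'),
    ('MAE', 'RMT', 'LR', 'rut'),
    ('MAE', 'RMT', 'LR', 'pae'),
    ('MAE', 'RMT', 'PR', 'ber'),
    ('MAE', 'RMT', 'PR', 'pal'),
    ('MAE', 'RMT', 'PR', 'evo'),
    ('MAE', 'RMT', 'PR', 'rut'),
    ('MAE', 'RMT', 'PR', 'pae'),
    ('MAE', 'RMT', 'SVR', 'ber'),
    ('MAE', 'RMT', 'SVR', 'pal'),
    ('MAE', 'RMT', 'SVR', 'evo'),
    ('MAE', 'RMT', 'SVR', 'rut'),
    ('MAE', 'RMT', 'SVR', 'pae'),
    ('MAE', 'RMT', 'ANN', 'ber'),
    ('MAE', 'RMT', 'ANN', 'pal'),
    ('MAE', 'RMT', 'ANN', 'evo'),
    ('MAE', 'RMT', 'ANN', 'rut'),
    ('MAE', 'RMT', 'ANN', 'pae'),
    ('MAE', 'RMT', 'PLS', 'ber'),
    ('MAE', 'RMT', 'PLS', 'pal'),
    ('MAE', 'RMT', 'PLS', 'evo'),
    ('MAE', 'RMT', 'PLS', 'rut'),
    ('MAE', 'RMT', 'PLS', 'pae'),
)


def recompute_improvement(measure: str, vs: str, base: str, compound: str) -> float:
    """Improvement percentage of MT over ``vs`` recomputed from the error tables."""
    ref = BENCHMARK_ERRORS[measure][(base, vs)][compound]
    new = BENCHMARK_ERRORS[measure][(base, "MT")][compound]
    return improvement(ref, new)


def recompute_improvement_table(measure: str, vs: str) -> pd.DataFrame:
    """Recomputed improvement table (compound rows x base-learner columns)."""
    data = {
        base: [recompute_improvement(measure, vs, base, c) for c in COMPOUNDS]
        for base in BASES
    }
    return pd.DataFrame(data, index=list(COMPOUNDS))
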