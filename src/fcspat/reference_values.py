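"""Published summary statistics for the seven drone-mapped survey plots.

These are the printed nearest-neighbor results for the 12 analyzed fairy
circle / Euphorbia patterns (plot name, point count, mean NN distance in m,
CV of NN distances in percent, Clark-Evans R, Monte-Carlo p-value, pattern
category). They serve as the comparison reference for the
``reproduce-table1`` command, which recomputes each row from the deposited
coordinate spreadsheet and reports per-cell deltas. They are reference
data, never a substitute for computation.
"""

from __future__ import annotations

PUBLISHED_TABLE1: list[dict] = [
    {"region": "Giribes", "label": "Gir-1 Fairy Circles", "n": 277,
     "mean_nn_m": 22.6, "cv_nn_pct": 22.4, "clark_evans_R": 1.51,
     "p_value": 0.002, "pattern": "Regular"},
    {"region": "Giribes", "label": "Gir-1 Euphorbias", "n": 130,
     "mean_nn_m": 19.8, "cv_nn_pct": 60.7, "clark_evans_R": 0.90,
     "p_value": 0.006, "pattern": "Clustered"},
    {"region": "Giribes", "label": "Gir-3 Fairy Circles", "n": 1143,
     "mean_nn_m": 12.0, "cv_nn_pct": 18.8, "clark_evans_R": 1.62,
     "p_value": 0.002, "pattern": "Regular"},
    {"region": "Brandberg", "label": "Bra-1 Fairy Circles", "n": 284,
     "mean_nn_m": 17.4, "cv_nn_pct": 42.7, "clark_evans_R": 1.17,
     "p_value": 0.002, "pattern": "Regular"},
    {"region": "Brandberg", "label": "Bra-1 Euphorbias", "n": 58,
     "mean_nn_m": 30.1, "cv_nn_pct": 56.4, "clark_evans_R": 0.92,
     "p_value": 0.066, "pattern": "Random"},
    {"region": "Brandberg", "label": "Bra-2 Fairy Circles", "n": 138,
     "mean_nn_m": 24.2, "cv_nn_pct": 51.4, "clark_evans_R": 1.14,
     "p_value": 0.036, "pattern": "Regular"},
    {"region": "Brandberg", "label": "Bra-2 Euphorbias", "n": 87,
     "mean_nn_m": 24.2, "cv_nn_pct": 65.2, "clark_evans_R": 0.90,
     "p_value": 0.024, "pattern": "Clustered"},
    {"region": "Brandberg", "label": "Bra-3 Fairy Circles", "n": 437,
     "mean_nn_m": 18.0, "cv_nn_pct": 21.1, "clark_evans_R": 1.50,
     "p_value": 0.002, "pattern": "Regular"},
    {"region": "Garub", "label": "Gar-1 Fairy Circles", "n": 113,
     "mean_nn_m": 26.6, "cv_nn_pct": 38.9, "clark_evans_R": 1.10,
     "p_value": 0.32, "pattern": "Random"},
    {"region": "Garub", "label": "Gar-1 Euphorbias", "n": 90,
     "mean_nn_m": 21.6, "cv_nn_pct": 95.3, "clark_evans_R": 0.80,
     "p_value": 0.002, "pattern": "Clustered"},
    {"region": "Garub", "label": "Gar-2 Fairy Circles", "n": 45,
     "mean_nn_m": 38.5, "cv_nn_pct": 55.5, "clark_evans_R": 0.91,
     "p_value": 0.074, "pattern": "Random"},
    {"region": "Garub", "label": "Gar-2 Euphorbias", "n": 358,
     "mean_nn_m": 14.5, "cv_nn_pct": 52.0, "clark_evans_R": 0.97,
     "p_value": 0.082, "pattern": "Random"},
]

#: Printed diameter groups (min, max, mean, n) used for in-survey arithmetic
#: such as the mega-circle vs dead-shrub size ratio (15.9 / 5.9 = 2.7).
PUBLISHED_DIAMETERS: dict[str, tuple[float, float, float, int]] = {
    "Gir1_FC": (13.0, 19.1, 15.9, 10),
    "Gir1_dead_Euphorbia": (4.2, 7.8, 5.9, 10),
    "Gir2_dead_Euphorbia": (4.2, 11.7, 8.6, 30),
    "Bra1_FC": (2.4, 2.9, 2.7, 10),
    "Bra1_dead_Euphorbia": (4.3, 7.2, 5.6, 10),
    "Bra2_dead_Euphorbia": (4.1, 7.2, 5.8, 10),
}
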