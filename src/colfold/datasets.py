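"""Small bundled datasets used by the worked examples and tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["md_reference_outcomes"]

# Final heavy-atom RMSD (Å, last sampled frame at 1 μs) and folding time
# (ns, None = never completely folded) of ten independent 1 μs MD folding
# simulations per construct of the (Gly-Pro-Pro)5 homotrimer: wild type
# with standard (0.5 kcal·mol⁻¹·Å⁻²) nucleus restraints, wild type with
# weak (0.05) restraints, and central Gly→Ala/Thr substitutions in one
# (G7aA/G7aT) or all three (G7abcA/G7abcT) chains.
_OUTCOMES = {
    "wild_type": [
        (1.4, 44), (2.5, 960), (1.6, 319), (1.4, 138), (1.5, 96),
        (1.4, 357), (1.7, 331), (7.8, None), (1.4, 95), (1.6, 45),
    ],
    "weak_restraints": [
        (14.7, None), (10.1, None), (1.6, 706), (2.5, 139), (11.2, None),
        (9.0, None), (7.9, None), (13.3, None), (1.9, 89), (1.7, 390),
    ],
    "G7aA": [
        (1.6, 879), (6.8, None), (7.6, None), (9.4, None), (2.4, 769),
        (13.3, None), (4.6, None), (11.8, None), (2.0, 905), (2.7, 635),
    ],
    "G7aT": [
        (5.9, None), (3.0, 475), (5.0, None), (2.9, 280), (2.9, 494),
        (1.9, 992), (9.8, None), (1.7, 494), (3.1, 428), (6.2, None),
    ],
    "G7abcA": [
        (3.9, 398), (10.8, None), (10.4, None), (3.9, 907), (8.4, None),
        (4.2, 83), (4.4, 555), (8.6, None), (3.7, 837), (4.0, 540),
    ],
    "G7abcT": [
        (4.8, 677), (15.4, None), (9.2, None), (4.8, None), (18.7, None),
        (6.2, None), (13.9, None), (5.1, None), (14.1, None), (9.1, None),
    ],
}


def md_reference_outcomes() -> pd.DataFrame:
    """Per-run outcomes of the published MD folding simulations.

    Columns: ``construct``, ``run`` (1-10), ``final_rmsd_A`` (heavy-atom
    RMSD vs. the native helix at the final frame) and ``folding_time_ns``
    (NaN when the peptide never folded completely within 1 μs). Used as a
    worked example for the outcome tabulator.
    """
    rows = []
    for construct, entries in _OUTCOMES.items():
        for run, (rmsd_a, t_ns) in enumerate(entries, start=1):
            rows.append(
                {
                    "construct": construct,
                    "run": run,
                    "final_rmsd_A": rmsd_a,
                    "folding_time_ns": np.nan if t_ns is None else float(t_ns),
                }
            )
    return pd.DataFrame(rows)
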