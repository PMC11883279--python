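"""Published comparative jump-kinematics values used as pipeline inputs.

These are printed summary statistics from the salticid jumping literature
(per-species means of body mass, peak acceleration, take-off velocity,
take-off duration and take-off angle).  They parameterize the synthetic
study conditions and support cross-species comparisons; none of the
pipeline's computed outputs are taken from here.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["SALTICID_KINEMATICS", "MASS_EXTREMES_MG", "species_row"]

#: Literature means per species/sex: body mass (mg), peak acceleration
#: (m/s^2), take-off velocity (m/s), take-off duration (ms), take-off
#: angle (deg).
SALTICID_KINEMATICS = pd.DataFrame(
    [
        ("Maratus splendens", "male", 4.9, 127.8, 0.84, 20.8, 25.08),
        ("Maratus splendens", "female", 10.4, 122.7, 0.81, 24.6, 20.89),
        ("Attulus pubescens", "male", 10.0, 51.3, 0.67, 13.06, 12.0),
        ("Habronattus conjunctus", "mixed", 14.5, 28.3, 0.48, 17.65, 18.7),
        ("Phidippus princeps", "female", 150.0, 51.4, 0.83, 16.15, 22.0),
        ("Phidippus regius", "female", 150.0, 36.07, 0.79, 22.19, 19.67),
    ],
    columns=[
        "species",
        "sex",
        "body_mass_mg",
        "peak_acceleration_m_per_s2",
        "takeoff_velocity_m_per_s",
        "takeoff_duration_ms",
        "takeoff_angle_deg",
    ],
)

#: Observed adult body-mass extremes in the M. splendens study population
#: (lightest male, heaviest female), mg.
MASS_EXTREMES_MG = {"lightest_male": 2.0, "heaviest_female": 13.2}


def species_row(species: str, sex: str | None = None) -> pd.Series:
    """Return the literature kinematics row for one species (and sex)."""
    df = SALTICID_KINEMATICS
    sel = df["species"] == species
    if sex is not None:
        sel &= df["sex"] == sex
    match = df[sel]
    if len(match) != 1:
        raise KeyError(f"no unique entry for {species!r} / {sex!r}")
    return match.iloc[0]
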