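"""Isotope-envelope model for singly charged tryptic peptides.

Peptide isotope patterns are predicted from mass alone using the averagine
model: a hypothetical "average" amino-acid residue (C4.9384 H7.7583 N1.3577
O1.4773 S0.0417, average mass 111.1254 Da) whose elemental composition is
scaled to the peptide mass.  The relative abundance of the k-th isotopologue
is approximated by a Poisson distribution whose rate is the expected number
of heavy-isotope substitutions, i.e. the summed +1-isotope abundance of all
atoms in the scaled composition.  This is the standard desk-scale
approximation for MALDI-TOF peptide envelopes; it places the crossover where
the second isotope peak overtakes the monoisotopic peak near 1.87 kDa.
"""

from __future__ import annotations

import numpy as np

#: Average spacing between adjacent isotope peaks of a singly charged
#: peptide (Da).  This is the averagine mean, slightly below the pure
#: 13C-12C difference (1.00335 Da) because 15N/2H substitutions contribute.
ISOTOPE_SPACING = 1.00235

#: Mass of a proton (Da); added to a neutral peptide mass to obtain the
#: singly protonated MH+ observed in MALDI.
PROTON_MASS = 1.007276

#: Averagine residue: average elemental composition per amino acid.
AVERAGINE_COMPOSITION = {
    "C": 4.9384,
    "H": 7.7583,
    "N": 1.3577,
    "O": 1.4773,
    "S": 0.0417,
}
AVERAGINE_MASS = 111.1254

#: Natural abundance of the +1 isotope of each element (13C, 2H, 15N, 17O, 33S).
_PLUS_ONE_ABUNDANCE = {
    "C": 0.0107,
    "H": 0.000115,
    "N": 0.00364,
    "O": 0.00038,
    "S": 0.0075,
}

#: Expected heavy-isotope substitutions per Da of peptide mass.
POISSON_RATE_PER_DA = sum(
    AVERAGINE_COMPOSITION[el] * _PLUS_ONE_ABUNDANCE[el] for el in AVERAGINE_COMPOSITION
) / AVERAGINE_MASS


def averagine_envelope(monoisotopic_mass: float, n_peaks: int = 4) -> list[tuple[float, float]]:
    """Predict the isotope envelope of a peptide from its monoisotopic mass.

    Parameters
    ----------
    monoisotopic_mass : float
        Neutral (or protonated — the difference is negligible for the
        pattern) monoisotopic mass in Da.  Must be positive.
    n_peaks : int
        Number of isotope peaks to return, ``k = 0 .. n_peaks - 1``.

    Returns
    -------
    list of (offset, relative_intensity)
        ``offset`` is ``k * ISOTOPE_SPACING`` Da from the monoisotopic peak;
        intensities follow the Poisson-approximated averagine distribution,
        normalised so the most intense peak equals 1.
    """
    if monoisotopic_mass <= 0:
        raise ValueError(f"monoisotopic_mass must be positive, got {monoisotopic_mass}")
    if n_peaks < 1:
        raise ValueError(f"n_peaks must be >= 1, got {n_peaks}")
    lam = POISSON_RATE_PER_DA * monoisotopic_mass
    k = np.arange(n_peaks)
    # Poisson pmf up to the common normalisation; stable for small n_peaks.
    log_w = k * np.log(lam) - np.cumsum(np.log(np.maximum(k, 1)))
    w = np.exp(log_w - log_w.max())
    return list(zip((k * ISOTOPE_SPACING).tolist(), w.tolist()))


def envelope_ratios(monoisotopic_mass: float, n_peaks: int = 4) -> np.ndarray:
    """Isotope intensities relative to the *monoisotopic* peak (index 0 == 1)."""
    env = averagine_envelope(monoisotopic_mass, n_peaks)
    w = np.array([i for _, i in env])
    return w / w[0]
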