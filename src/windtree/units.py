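"""Unit conventions and conversion helpers.

Internally the growth model works in grams and centimetres (the scale of
organs and allometric rules) while the mechanical model works in SI (metres,
newtons, pascals).  All conversions between the two live here.
"""

G_GRAVITY = 9.81  # m s^-2

CM_PER_M = 100.0
CM2_PER_M2 = 1.0e4
G_PER_KG = 1000.0


def grams_to_newtons(mass_g: float) -> float:
    """Weight (N) of a mass given in grams."""
    return mass_g / G_PER_KG * G_GRAVITY


def cm_to_m(x_cm: float) -> float:
    return x_cm / CM_PER_M


def m_to_cm(x_m: float) -> float:
    return x_m * CM_PER_M


def cm2_to_m2(a_cm2: float) -> float:
    return a_cm2 / CM2_PER_M2
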