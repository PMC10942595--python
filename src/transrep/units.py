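"""Unit conversion helpers.

Canonical internal units are nanomolar (nM) and minutes for all molecular
quantities.  Inducer doses are handled in micromolar (the scale plate-reader
dose series are reported on) and growth rates in per-hour; these helpers
convert exactly at the package boundary so no module mixes scales silently.
"""

MIN_PER_H = 60.0


def uM_to_nM(x: float) -> float:
    return x * 1e3


def nM_to_uM(x: float) -> float:
    return x * 1e-3


def mM_to_nM(x: float) -> float:
    return x * 1e6


def per_h_to_per_min(rate: float) -> float:
    return rate / MIN_PER_H


def per_min_to_per_h(rate: float) -> float:
    return rate * MIN_PER_H


def s_to_min(t: float) -> float:
    return t / 60.0


def min_to_s(t: float) -> float:
    return t * 60.0
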