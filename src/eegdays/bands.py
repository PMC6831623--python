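"""Canonical frequency-band definitions (Hz, inclusive edges)."""

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 50.0),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")
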