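"""Canonical EEG frequency bands used throughout the pipeline."""

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with lower/upper edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges: {self.lo}-{self.hi} Hz")


#: The four canonical bands the analysis is run in.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}

#: Broadband filter applied to the raw record before band splitting.
BROADBAND = BandSpec("broadband", 1.0, 40.0)
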