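"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .cli_io import read_studies
from .effect_transforms import StudyData


def load_bem_2011() -> StudyData:
    """Nine precognition experiments (Bem, 2011), Cohen's d scale.

    Standard errors are back-calculated from the reported one-sample
    designs, se = sqrt(1/N + d^2/(2N)); the worked-example results in
    the docs are computed from this table.
    """
    with resources.as_file(resources.files("bmameta.data") / "bem_2011.csv") as p:
        return read_studies(p, scale="d")
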