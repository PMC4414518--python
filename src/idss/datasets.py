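"""Packaged example data."""

from importlib import resources

from .io import read_counts
from .types import AssemblageCounts


def pfg_ceramics() -> AssemblageCounts:
    """The 20 late prehistoric decorated ceramic assemblages from the
    Memphis and St. Francis areas of the Mississippi River Valley
    (Phillips-Ford-Griffin survey collections),
    described by counts of 10 decorated types. This is the worked example
    dataset for the whole pipeline."""
    path = resources.files("idss").joinpath("data/pfg_ceramics.tsv")
    with resources.as_file(path) as p:
        return read_counts(p)
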