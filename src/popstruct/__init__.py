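"""popstruct: continental-ancestry assignment and population-structure
analysis for genotype cohorts, with a synthetic-cohort rehearsal mode."""

from importlib import resources
from pathlib import Path

from .cohort import MISSING, GenotypeMatrix

__version__ = "0.1.0"


def example_fixture(name: str) -> Path:
    """Path to a bundled user-replaceable fixture file.

    Available: ``region_map_example.csv`` (country -> region mapping) and
    ``high_ld_regions_example.bed`` (exclusion regions).
    """
    path = resources.files("popstruct").joinpath("data", name)
    with resources.as_file(path) as p:
        if not p.exists():
            raise FileNotFoundError(f"no bundled fixture named {name!r}")
        return p


__all__ = ["GenotypeMatrix", "MISSING", "example_fixture", "__version__"]
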