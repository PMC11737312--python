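"""Packaged reference tables.

Two small CSVs ship with the package: species-mean morphometrics with
dissection-calculated bite forces for 19 parrot species, and
transducer-measured plus scar-predicted bite forces for nine species. They
anchor the allometric regressions, the ratio checks and the
method-comparison analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_species_means", "load_bite_force_comparison"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("parrotbite.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def load_species_means() -> pd.DataFrame:
    """19 parrot species: body/skull mass, skull length, one-side jaw muscle
    mass, calculated bite force and the bite-force:body-mass ratio."""
    return _load("parrot_species_means.csv")


def load_bite_force_comparison() -> pd.DataFrame:
    """Nine species with transducer-measured bite forces and, where a skull
    image existed, scar-predicted bite forces and the matching ratios."""
    return _load("measured_predicted_bite_forces.csv")
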