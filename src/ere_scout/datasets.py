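"""Packaged reference data: myostatin-promoter genotype counts by breed.

Genotype counts of the ERE1 insertion in the myostatin promoter for five
domestic-horse breeds, Przewalski's horse, and three sport-aptitude
groups.  Panel A covers breed surveys, panel B groups bred for different
racing disciplines.  Counts of individuals by genotype (+/+ carries the
insertion on both chromosomes).
"""

from __future__ import annotations

import pandas as pd

_TABLE1 = [
    # panel, group, n, +/+, +/-, -/-
    ("A", "Quarter Horse", 20, 9, 5, 6),
    ("A", "Andalusian", 20, 0, 3, 17),
    ("A", "Lipizzaner", 23, 0, 0, 23),
    ("A", "Norwegian Fjord", 20, 0, 0, 20),
    ("A", "Icelandic Pony", 19, 0, 0, 19),
    ("A", "Przewalski's Horse", 20, 0, 0, 20),
    ("B", "Show Jumpers", 30, 0, 1, 29),
    ("B", "Italian Trotters", 90, 0, 0, 90),
    ("B", "Unselected Italian Thoroughbreds", 75, 18, 29, 28),
    ("B", "Elite Italian Thoroughbreds", 117, 33, 69, 15),
]


def myostatin_genotype_counts() -> pd.DataFrame:
    """Genotype counts at the myostatin-promoter insertion, by group."""
    return pd.DataFrame(
        _TABLE1, columns=["panel", "group", "n", "n_pp", "n_pm", "n_mm"]
    )
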