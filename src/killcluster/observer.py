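"""Double-observer ground-truthing concordance.

A subset of clusters is classified independently twice: an *initial*
investigation soon after the cluster starts (visit 1) and the *standard*
ground-truthing visit 2–60 days later (visit 2).  The concordance summary
reports the discordance rate, which observer recorded the absence in each
discordant pair, and the prey composition of the double-visited clusters:

* ``large`` — feeding found and prey above the 23.7 kg size threshold,
* ``small_ungulate`` — wild ungulate below the threshold (fawns),
* ``non_ungulate`` — other prey (e.g., meso-carnivores),
* ``none`` — neither visit found prey remains.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["ConcordanceSummary", "concordance_summary"]


@dataclass(frozen=True)
class ConcordanceSummary:
    n_pairs: int
    n_discordant: int
    discordance_rate: float
    initial_missed: int   # visit-1 observer recorded absence, visit 2 found prey
    standard_missed: int  # visit-2 observer recorded absence, visit 1 found prey
    composition: dict     # proportions over {large, small_ungulate, non_ungulate, none}
    discordant_small_or_nonungulate: int
    discordant_large: int

    def to_dict(self) -> dict:
        return asdict(self)


def concordance_summary(pairs: pd.DataFrame) -> ConcordanceSummary:
    """Summarize agreement between initial and standard visits.

    ``pairs`` is a double-observer table as returned by
    :func:`killcluster.io.read_cluster_tables` with dialect
    ``double_observer``.
    """
    n = len(pairs)
    if n == 0:
        raise ValueError("empty double-observer table")
    v1 = pairs["visit1_feeding"].astype(bool)
    v2 = pairs["visit2_feeding"].astype(bool)
    large = pairs["large_prey"].astype(bool)
    ungulate = pairs["wild_ungulate"].astype(bool)

    discordant = v1 != v2
    initial_missed = int((~v1 & v2).sum())
    standard_missed = int((v1 & ~v2).sum())

    found = v1 | v2
    comp_counts = {
        "large": int((found & large).sum()),
        "small_ungulate": int((found & ungulate & ~large).sum()),
        "non_ungulate": int((found & ~ungulate).sum()),
        "none": int((~found).sum()),
    }
    composition = {k: v / n for k, v in comp_counts.items()}
    return ConcordanceSummary(
        n_pairs=n,
        n_discordant=int(discordant.sum()),
        discordance_rate=float(discordant.mean()),
        initial_missed=initial_missed,
        standard_missed=standard_missed,
        composition=composition,
        discordant_small_or_nonungulate=int((discordant & ~large).sum()),
        discordant_large=int((discordant & large).sum()),
    )
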