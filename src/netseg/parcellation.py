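"""Reference parcellation: 300 ROIs grouped into 14 functional networks.

The reference set assigns each of 300 whole-brain regions of interest to one
of 14 networks; ROIs labeled ``Unassigned`` are carried through connectivity
matrices but excluded from network-level statistics, leaving 13 analysis
networks.  All downstream code is agnostic to the number of ROIs or networks,
so reduced parcellations can be used for fast tests.
"""

from __future__ import annotations

import pandas as pd

#: Network sizes of the reference 300-ROI set.  The DefaultMode (65),
#: SomatomotorDorsal (40) and DorsalAttention (14) counts are fixed by the
#: reference set; the remaining counts are plausible allocations that sum
#: to 300.
NETWORK_SIZES: dict[str, int] = {
    "SomatomotorDorsal": 40,
    "SomatomotorLateral": 9,
    "CinguloOpercular": 30,
    "Auditory": 12,
    "DefaultMode": 65,
    "ParietalMedial": 6,
    "Visual": 39,
    "FrontoParietal": 33,
    "Salience": 9,
    "VentralAttention": 12,
    "DorsalAttention": 14,
    "MedialTemporalLobe": 6,
    "Reward": 8,
    "Unassigned": 17,
}

NETWORKS: tuple[str, ...] = tuple(NETWORK_SIZES)
UNASSIGNED = "Unassigned"
#: The 13 networks entering network-level analyses.
ANALYSIS_NETWORKS: tuple[str, ...] = tuple(n for n in NETWORKS if n != UNASSIGNED)


def default_parcellation() -> pd.DataFrame:
    """Return the reference 300-ROI parcellation table.

    Returns
    -------
    pandas.DataFrame
        Columns ``roi_id`` (ROI001..ROI300) and ``network``.
    """
    rows = []
    i = 0
    for network, size in NETWORK_SIZES.items():
        for _ in range(size):
            i += 1
            rows.append((f"ROI{i:03d}", network))
    return pd.DataFrame(rows, columns=["roi_id", "network"])


def validate_parcellation(parc: pd.DataFrame) -> pd.DataFrame:
    """Check a parcellation table: required columns, unique ROI ids."""
    for col in ("roi_id", "network"):
        if col not in parc.columns:
            raise ValueError(f"parcellation is missing column {col!r}")
    if parc["roi_id"].duplicated().any():
        dups = parc.loc[parc["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValueError(f"duplicate ROI ids in parcellation: {dups}")
    return parc


def analysis_networks(parc: pd.DataFrame) -> list[str]:
    """Networks present in *parc* excluding Unassigned, in first-seen order."""
    seen = parc["network"].drop_duplicates().tolist()
    return [n for n in seen if n != UNASSIGNED]


def write_parcellation(parc: pd.DataFrame, path) -> None:
    validate_parcellation(parc).to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> pd.DataFrame:
    return validate_parcellation(pd.read_csv(path, sep="\t"))
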