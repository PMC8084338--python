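"""ICeChIP spike-in calibration: barcode enrichment, histone modification
density (HMD) and antibody specificity.

Barcoded semisynthetic nucleosome standards are modelled as extra contigs of
the reference. For each modification species, the mean IP depth of its
barcode contigs is summed and divided by the same sum in the Input, giving
the species enrichment E_i; the targeted species' value is the target
enrichment E_t. Per-locus histone modification density is then

    HMD(%) = IP / (E_t * Input) * 100

with regions of zero Input set to 0, and specificity of species i is
E_i / E_t * 100 (exactly 100 for the target itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CalibrantTable",
    "read_calibrant_table",
    "barcode_enrichment",
    "hmd_track",
    "specificity",
]

DenseTrack = Mapping[str, np.ndarray]


@dataclass
class CalibrantTable:
    """Barcode contig -> modification species map with one flagged target."""

    barcodes: pd.DataFrame  # columns: contig, species, is_target

    def __post_init__(self):
        required = {"contig", "species", "is_target"}
        if not required.issubset(self.barcodes.columns):
            raise ValueError(f"calibrant table needs columns {sorted(required)}")
        targets = self.barcodes.loc[self.barcodes.is_target, "species"].unique()
        if len(targets) != 1:
            raise ValueError(
                f"exactly one species must be flagged target, got {list(targets)}"
            )

    @property
    def target_species(self) -> str:
        return str(self.barcodes.loc[self.barcodes.is_target, "species"].iloc[0])

    @property
    def species(self) -> List[str]:
        return list(dict.fromkeys(self.barcodes["species"]))


def read_calibrant_table(path: str, target_species: str) -> CalibrantTable:
    """Plain-text two-column (barcode contig, species) table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, species = line.split()[:2]
            rows.append((contig, species, species == target_species))
    df = pd.DataFrame(rows, columns=["contig", "species", "is_target"])
    if not df.is_target.any():
        raise ValueError(f"target species {target_species!r} not in table")
    return CalibrantTable(df)


def barcode_enrichment(
    ip: DenseTrack, input_: DenseTrack, table: CalibrantTable
) -> Tuple[Dict[str, float], float]:
    """Per-species enrichment E_i and the target enrichment E_t.

    Each barcode contributes its mean per-base depth; per species these means
    are summed in IP and in Input, and E_i is the ratio of the sums (sum
    before ratio, not ratio per barcode).
    """
    e: Dict[str, float] = {}
    for species, sub in table.barcodes.groupby("species", sort=False):
        ip_sum = 0.0
        in_sum = 0.0
        for contig in sub["contig"]:
            if contig not in ip or contig not in input_:
                raise KeyError(f"barcode contig {contig!r} missing from a track")
            ip_sum += float(np.mean(ip[contig]))
            in_sum += float(np.mean(input_[contig]))
        if in_sum == 0.0:
            raise ZeroDivisionError(
                f"species {species!r}: zero Input barcode depth, enrichment undefined"
            )
        e[str(species)] = ip_sum / in_sum
    return e, e[table.target_species]


def hmd_track(
    ip: DenseTrack,
    input_: DenseTrack,
    e_t: float,
    cap: Optional[float] = None,
    genomic_contigs: Optional[List[str]] = None,
) -> Dict[str, np.ndarray]:
    """Per-base histone modification density (%) from IP and Input tracks.

    Bases with zero Input are set to 0. ``cap`` clamps values from above
    (promoter-profile analyses use cap=100, since >100% density is
    impossible); the raw track is uncapped by default. ``genomic_contigs``
    restricts output (e.g. to exclude barcode contigs).
    """
    if e_t <= 0:
        raise ValueError("target enrichment must be positive")
    contigs = genomic_contigs if genomic_contigs is not None else list(ip.keys())
    out: Dict[str, np.ndarray] = {}
    for contig in contigs:
        ip_a = np.asarray(ip[contig], dtype=np.float64)
        in_a = np.asarray(input_[contig], dtype=np.float64)
        if ip_a.shape != in_a.shape:
            raise ValueError(f"contig {contig!r}: IP/Input length mismatch")
        hmd = np.zeros_like(ip_a)
        nz = in_a != 0.0
        hmd[nz] = ip_a[nz] / (e_t * in_a[nz]) * 100.0
        if cap is not None:
            np.minimum(hmd, cap, out=hmd)
        out[contig] = hmd
    return out


def specificity(e: Mapping[str, float], e_t: float) -> Dict[str, float]:
    """Per-species pulldown specificity as percent of target enrichment."""
    if e_t <= 0:
        raise ValueError("target enrichment must be positive")
    return {s: v / e_t * 100.0 for s, v in e.items()}
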