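"""Arrest-peptide force-profile quantification.

In a force-profile assay a stalling arrest peptide is appended to a
nascent chain of defined length; folding-generated tension restarts
stalled translation, so the fraction of full-length product,

    f_FL = sum(FL band intensities) / (sum(FL) + sum(AR)),

reports the pulling force at that chain length.  This module turns
band-intensity tables into per-length f_FL profiles with replicate SEM
and calls contiguous high-tension regions above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BandQuantification:
    """FL and AR band intensities for one construct length and replicate.

    Products that run as double bands are recorded as multiple
    intensities and summed before the ratio is taken.
    """

    length_aa: int
    replicate: str
    fl: tuple[float, ...]
    ar: tuple[float, ...]

    def __post_init__(self) -> None:
        self.fl = tuple(float(v) for v in np.atleast_1d(self.fl))
        self.ar = tuple(float(v) for v in np.atleast_1d(self.ar))
        if self.length_aa <= 0:
            raise ValueError("construct length must be positive")
        if any(v < 0 for v in self.fl + self.ar):
            raise ValueError("band intensities must be nonnegative")


@dataclass
class ForceProfile:
    """Mean f_FL vs nascent-chain length with replicate SEM."""

    lengths: np.ndarray
    f_fl: np.ndarray
    sem: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.f_fl = np.asarray(self.f_fl, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("lengths must be strictly increasing")
        if np.any((self.f_fl < 0) | (self.f_fl > 1)):
            raise ValueError("f_FL must lie in [0, 1]")
        if np.any(self.sem < 0):
            raise ValueError("SEM must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_aa": self.lengths,
                "f_FL": self.f_fl,
                "sem": self.sem,
                "n": self.n_replicates,
            }
        )


def fraction_full_length(q: BandQuantification) -> float:
    """f_FL = sum(FL) / (sum(FL) + sum(AR)); double bands summed first."""
    fl, ar = sum(q.fl), sum(q.ar)
    total = fl + ar
    if total <= 0:
        raise ValueError(
            f"all band intensities are zero for length {q.length_aa}, replicate {q.replicate}"
        )
    return fl / total


def build_force_profile(quantifications: list[BandQuantification]) -> ForceProfile:
    """Per-length mean f_FL and SEM (= sd/sqrt(n)) across replicates.

    A single replicate yields SEM = 0.  Duplicate (length, replicate)
    pairs are rejected.
    """
    if not quantifications:
        raise ValueError("no band quantifications")
    seen = set()
    for q in quantifications:
        key = (q.length_aa, q.replicate)
        if key in seen:
            raise ValueError(f"duplicate (length, replicate) pair {key}")
        seen.add(key)
    df = pd.DataFrame(
        {
            "length": [q.length_aa for q in quantifications],
            "f": [fraction_full_length(q) for q in quantifications],
        }
    )
    grouped = df.groupby("length")["f"]
    mean = grouped.mean()
    n = grouped.count()
    sd = grouped.std(ddof=1).fillna(0.0)
    sem = sd / np.sqrt(n)
    return ForceProfile(
        lengths=mean.index.to_numpy(),
        f_fl=mean.to_numpy(),
        sem=sem.to_numpy(),
        n_replicates=n.to_numpy(),
    )


def call_high_tension_regions(
    profile: ForceProfile,
    threshold: float = 0.4,
    min_run: int = 2,
    bridge_single_gaps: bool = True,
) -> list[tuple[int, int]]:
    """Maximal runs of sampled lengths with mean f_FL >= threshold.

    Runs spanning fewer than ``min_run`` sampled lengths are discarded.
    With ``bridge_single_gaps`` a single sub-threshold sampled length is
    bridged when both flanking lengths exceed the threshold (a transient
    force relief inside an otherwise continuous high-tension region).
    Returns (start_aa, end_aa) pairs in construct-length units.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if profile.lengths.size == 0:
        raise ValueError("empty profile")
    above = profile.f_fl >= threshold
    if bridge_single_gaps:
        above = above.copy()
        for i in range(1, above.size - 1):
            if not above[i] and above[i - 1] and above[i + 1]:
                above[i] = True
    regions = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, above.size - 1))
    out = []
    for i0, i1 in regions:
        if i1 - i0 + 1 >= min_run:
            out.append((int(profile.lengths[i0]), int(profile.lengths[i1])))
    return out


def load_band_table(path) -> list[BandQuantification]:
    """Read a band-intensity CSV: length_aa, replicate, band_type, intensity.

    One row per band; FL/AR double bands appear as repeated rows.
    """
    df = pd.read_csv(path)
    required = {"length_aa", "replicate", "band_type", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    out = []
    for (length, rep), sub in df.groupby(["length_aa", "replicate"]):
        fl = tuple(sub.loc[sub["band_type"] == "FL", "intensity"])
        ar = tuple(sub.loc[sub["band_type"] == "AR", "intensity"])
        out.append(BandQuantification(length_aa=int(length), replicate=str(rep), fl=fl, ar=ar))
    return out


def write_band_table(quantifications: list[BandQuantification], path) -> None:
    rows = []
    for q in quantifications:
        for v in q.fl:
            rows.append((q.length_aa, q.replicate, "FL", v))
        for v in q.ar:
            rows.append((q.length_aa, q.replicate, "AR", v))
    pd.DataFrame(rows, columns=["length_aa", "replicate", "band_type", "intensity"]).to_csv(
        path, index=False
    )
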