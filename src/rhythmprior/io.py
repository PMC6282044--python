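"""CSV interval I/O and the synthetic fixture distributions.

The interval CSV dialect is ``chain_id,generation,position,ioi_ms``: one row
per interval, positions 0-based within a (chain_id, generation) sequence,
UTF-8, values written with nanosecond precision so round trips are lossless
to 1e-9 ms.

The fixture panels emulate four archetypal interval distributions:

- ``B``: uniform on (100, 1000) ms — the random starting material of an
  iterated-reproduction experiment;
- ``C``: a 3-centroid Gaussian mixture with centroids drawn uniformly in
  (200, 1000) ms and SDs drawn independently of the means — multimodality
  without any timing constraint;
- ``D``: the same kind of centroids but SDs tied to means by the scalar
  constraint sigma = s * mu;
- ``E``: scalar-constraint mixture at centroids (200, 400, 800) ms — scalar
  timing AND small-integer ratios between adjacent centroids.

Panel C's "no further assumption" SDs are drawn uniformly in (5, 80) ms; the
choice is illustrative only and documented as such.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CategorySystem
from .errors import ParameterError
from .mixture import IOISequence, _as_rng, sample_iois, sample_positive_normal

__all__ = ["read_iois", "write_iois", "make_fixture", "CSV_COLUMNS"]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["chain_id", "generation", "position", "ioi_ms"]


def write_iois(sequences: Iterable[IOISequence] | IOISequence, path) -> None:
    """Write sequences to the interval CSV dialect (lossless to 1e-9 ms)."""
    if isinstance(sequences, IOISequence):
        sequences = [sequences]
    frames = []
    for seq in sequences:
        frames.append(
            pd.DataFrame(
                {
                    "chain_id": seq.chain_id,
                    "generation": seq.generation,
                    "position": np.arange(len(seq)),
                    "ioi_ms": seq.iois,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CSV_COLUMNS)
    )
    out.to_csv(path, index=False, float_format="%.9f")


def read_iois(path) -> list[IOISequence]:
    """Read interval sequences from the CSV dialect.

    Rows are grouped by (chain_id, generation) and ordered by position.
    Malformed headers, non-numeric cells and non-positive durations are
    rejected with the offending row number (1-based, header = row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"chain_id": str})
    if list(df.columns) != CSV_COLUMNS:
        raise ParameterError(
            f"{path}: expected header {','.join(CSV_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df.empty:
        logger.warning("%s: empty interval file", path)
        return []
    iois = pd.to_numeric(df["ioi_ms"], errors="coerce")
    bad = df.index[iois.isna() | (iois <= 0)]
    if len(bad):
        raise ParameterError(
            f"{path}: non-numeric or non-positive ioi_ms at row(s) "
            f"{[int(i) + 2 for i in bad[:10]]}"
        )
    df["ioi_ms"] = iois
    sequences = []
    for (chain_id, generation), grp in df.groupby(
        ["chain_id", "generation"], sort=True
    ):
        grp = grp.sort_values("position")
        sequences.append(
            IOISequence(
                grp["ioi_ms"].to_numpy(),
                chain_id=str(chain_id),
                generation=int(generation),
            )
        )
    return sequences


def make_fixture(panel: str, n: int = 1000, seed=None, s: float = 0.025) -> IOISequence:
    """Draw n intervals from one of the archetypal panel distributions (B-E)."""
    if n < 1:
        raise ParameterError(f"fixture size must be at least 1, got {n}")
    rng = _as_rng(seed)
    panel = str(panel).upper()
    if panel == "B":
        return IOISequence(rng.uniform(100.0, 1000.0, size=n), chain_id="panelB")
    if panel in ("C", "D"):
        centroids = np.sort(rng.uniform(200.0, 1000.0, size=3))
        sds = rng.uniform(5.0, 80.0, size=3) if panel == "C" else s * centroids
        ks = rng.integers(0, 3, size=n)
        return IOISequence(
            sample_positive_normal(rng, centroids[ks], sds[ks]),
            chain_id=f"panel{panel}",
        )
    if panel == "E":
        system = CategorySystem(means=(200.0, 400.0, 800.0), s=s)
        return sample_iois(system, n, seed=rng, chain_id="panelE")
    raise ParameterError(f"unknown fixture panel {panel!r}; expected B, C, D or E")
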