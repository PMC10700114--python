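"""Demographic-inference input preparation and output scaling.

Sequential-coalescent inference (MSMC2-style) on a single diploid genome
needs three things this module provides:

* a recombination-rate estimate to set the rho/mu ratio — important in
  taxa where recombination outpaces mutation (achiasmatic-female
  butterflies recombine only in males);
* multihetsep input files: heterozygous positions with the count of
  callable sites since the previous one, plus the per-contig mask BEDs;
* conversion of the scaled inference output into natural units:
  with per-generation mutation rate mu and generation time g,
  ``years = t/mu * g`` and ``Ne = 1/(2 mu lambda)`` for each scaled time
  boundary t and coalescence rate lambda. These conventions are stated in
  output headers since they differ across tools.
"""
from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CallableMask

__all__ = [
    "RecombinationModel",
    "DemographyStep",
    "BARONIA_PRESET",
    "recombination_rate",
    "rho_over_mu",
    "write_multihetsep",
    "parse_multihetsep",
    "bootstrap_multihetsep",
    "scale_msmc",
]

# Swallowtail-style constants: 406 Mb genome in 30 chromosomes, one
# crossover per tetrad per male meiosis, females achiasmatic. All values
# overridable.
BARONIA_PRESET = {
    "C": 30,
    "L": 406_000_000,
    "x": 1.0,
    "mu": 1.3e-9,
    "gen_time": 1.0,
    "msmc_rho_over_mu_setting": 10,
}


@dataclass(frozen=True, slots=True)
class RecombinationModel:
    C: int                 # chromosome count
    L: int                 # genome length, bp
    x: float               # crossovers per tetrad per male meiosis
    sex_averaging: str     # "male_only" | "averaged"
    map_morgans: float
    r: float               # per-site per-generation recombination rate


@dataclass(frozen=True, slots=True)
class DemographyStep:
    time_years: float
    ne: float


def recombination_rate(
    C: int, L: int, x: float = 1.0, sex_averaging: str = "male_only"
) -> RecombinationModel:
    """Per-site recombination rate from a crossover-count argument.

    A single crossover per tetrad recombines half the meiotic products, so
    the male map length is ``C * x * 0.5`` Morgans. ``male_only`` divides
    by L (the rate experienced on a male-transmitted chromosome);
    ``averaged`` divides by 2L, the sex-averaged rate when females do not
    recombine.
    """
    if C <= 0 or L <= 0 or x <= 0:
        raise ValueError("C, L and x must all be positive")
    if sex_averaging not in ("male_only", "averaged"):
        raise ValueError(f"unknown sex_averaging {sex_averaging!r}")
    map_morgans = C * x * 0.5
    denom = L if sex_averaging == "male_only" else 2 * L
    return RecombinationModel(
        C=C, L=L, x=x, sex_averaging=sex_averaging,
        map_morgans=map_morgans, r=map_morgans / denom,
    )


def rho_over_mu(r: float, mu: float) -> float:
    if mu <= 0:
        raise ValueError("mu must be positive")
    return r / mu


def write_multihetsep(
    het_sites: Mapping[str, Sequence[tuple[int, str]]],
    mask: CallableMask,
    path,
) -> None:
    """Write a multihetsep file: contig, 1-based position, callable sites
    since the previous row, genotype string.

    ``het_sites`` maps contig -> sorted (0-based position, genotype
    string) pairs; every site must lie inside the mask. The first row of a
    contig counts callable sites from the contig's first masked position.
    An empty site set yields an empty (but valid) file.
    """
    with open(path, "w") as fh:
        for contig in sorted(het_sites):
            prev0 = 0  # count window starts at the contig origin
            for pos0, gt in sorted(het_sites[contig]):
                if not mask.contains(contig, pos0):
                    raise ValueError(f"het site outside mask: {contig}:{pos0 + 1}")
                called = mask.overlap_bp(contig, prev0, pos0 + 1)
                fh.write(f"{contig}\t{pos0 + 1}\t{called}\t{gt}\n")
                prev0 = pos0 + 1


def parse_multihetsep(path) -> list[tuple[str, int, int, str]]:
    """Read back (contig, 1-based pos, called-since-last, genotype) rows."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, pos, called, gt = line.rstrip("\n").split("\t")
            rows.append((contig, int(pos), int(called), gt))
    return rows


def bootstrap_multihetsep(
    rows: Sequence[tuple[str, int, int, str]],
    rng: np.random.Generator,
    chunk_bp: int = 5_000_000,
    n_bootstraps: int = 10,
) -> list[list[tuple[str, int, int, str]]]:
    """Block bootstrap: resample genomic chunks with replacement.

    Rows are grouped into chunks of ``chunk_bp`` by position; each
    replicate draws chunks with replacement and re-threads them onto
    pseudo-contigs with positions shifted to stay increasing.
    """
    chunks: dict[tuple[str, int], list[tuple[str, int, int, str]]] = {}
    for row in rows:
        key = (row[0], (row[1] - 1) // chunk_bp)
        chunks.setdefault(key, []).append(row)
    keys = sorted(chunks)
    if not keys:
        return [[] for _ in range(n_bootstraps)]
    replicates = []
    for _ in range(n_bootstraps):
        drawn = rng.integers(0, len(keys), size=len(keys))
        rep: list[tuple[str, int, int, str]] = []
        offset = 0
        for k in drawn:
            chunk = chunks[keys[k]]
            base = (chunk[0][1] - 1) // chunk_bp * chunk_bp
            for contig, pos, called, gt in chunk:
                rep.append(("bootstrap_1", pos - base + offset, called, gt))
            offset += chunk_bp
        replicates.append(rep)
    return replicates


def scale_msmc(
    segments: Iterable[tuple[float, float]] | pd.DataFrame,
    mu: float,
    gen_time: float = 1.0,
) -> pd.DataFrame:
    """Convert scaled (left time boundary, coalescence rate) segments to
    (years, Ne).

    Scaled times are in units of expected mutations per site; dividing by
    mu gives generations, times ``gen_time`` gives years. The coalescence
    rate lambda maps to ``Ne = 1/(2 mu lambda)``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if isinstance(segments, pd.DataFrame):
        pairs = list(zip(segments.iloc[:, 0], segments.iloc[:, 1]))
    else:
        pairs = list(segments)
    times = [t for t, _ in pairs]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("scaled times must be strictly increasing")
    rows = []
    for t, lam in pairs:
        if lam <= 0:
            raise ValueError("coalescence rate must be positive")
        rows.append(
            {
                "time_years": t / mu * gen_time,
                "ne": 1.0 / (2.0 * mu * lam),
            }
        )
    return pd.DataFrame(rows, columns=["time_years", "ne"])


def write_scaled(df: pd.DataFrame, path, mu: float, gen_time: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# years = t_scaled/mu * gen_time; Ne = 1/(2*mu*lambda); "
                 f"mu={mu:g}, gen_time={gen_time:g}\n")
        df.to_csv(fh, sep="\t", index=False)
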