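"""Synthetic UMI-tagged libraries with known ground truth.

The generator emulates the data structure the consensus method assumes:
``n_molecules`` original molecules, each tagged with a distinct random
barcode and amplified into a number of duplicate reads. Every emitted base
is substituted independently at a per-base rate (UMI and insert rates are
separate), with the substitute drawn uniformly from the three alternatives.
Correct bases carry ``quality_high``, substituted bases ``quality_low`` — a
deliberately two-level quality model that keeps the frequency-vs-quality
consensus criterion exercisable with controlled contrasts. No indels and no
amplification jackpots are modeled; reads are fixed-length by construction.

Truth barcodes are drawn by rejection sampling so that every pair is at
Hamming distance >= ``min_umi_separation``, which makes "one cluster per
molecule" a guarantee rather than a likelihood when merging with a distance
threshold below half the separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fastq_io import ReadPair, ReadRecord, write_fastq
from .merging import hamming

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of the synthetic library.

    ``duplicates_per_molecule`` is either a fixed integer or an inclusive
    ``(low, high)`` uniform range. Defaults describe a small but realistic
    targeted-amplicon run: 200 molecules, 12-nt barcodes, 50-bp inserts,
    8-30 duplicates each, barcode/insert substitution rates of 0.2%/0.5%
    per base, and Illumina-like qualities (Q37 correct, Q14 errored).
    """

    n_molecules: int = 200
    umi_length: int = 12
    insert_length: int = 50
    duplicates_per_molecule: int | tuple[int, int] = (8, 30)
    umi_error_rate: float = 0.002
    insert_error_rate: float = 0.005
    quality_high: int = 37
    quality_low: int = 14
    paired: bool = False
    dual_umi: bool = False
    min_umi_separation: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.umi_error_rate < 0.5 and 0 <= self.insert_error_rate < 0.5):
            raise ValueError("error rates must lie in [0, 0.5)")
        for q in (self.quality_high, self.quality_low):
            if not 0 <= q <= 41:
                raise ValueError("quality values must lie in [0, 41]")
        if self.dual_umi and not self.paired:
            raise ValueError("dual_umi=True requires paired=True")


@dataclass
class TruthRecord:
    molecule_id: int
    true_umi: str
    true_insert: str
    true_insert_r2: str | None
    n_duplicates: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _separated_umis(
    rng: np.random.Generator, n: int, length: int, min_sep: int
) -> list[str]:
    umis: list[str] = []
    attempts = 0
    while len(umis) < n:
        cand = _random_seq(rng, length)
        if all(hamming(cand, u) >= min_sep for u in umis):
            umis.append(cand)
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(
                "could not draw sufficiently separated UMIs; use longer UMIs "
                "or fewer molecules"
            )
    return umis


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, q_high: int, q_low: int
) -> tuple[str, tuple[int, ...]]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute uniformly among the 3 alternative bases
        idx = np.nonzero(hit)[0]
        cur = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    quals = np.where(hit, q_low, q_high)
    return arr.tobytes().decode("ascii"), tuple(int(q) for q in quals)


def simulate_reads(
    sim: SimConfig,
) -> tuple[list[ReadRecord] | list[ReadPair], list[TruthRecord]]:
    """Generate the library in memory; fully reproducible from ``sim.seed``."""
    rng = np.random.default_rng(sim.seed)
    umi_total = sim.umi_length * (2 if sim.dual_umi else 1)
    umis = _separated_umis(rng, sim.n_molecules, umi_total, sim.min_umi_separation)

    if isinstance(sim.duplicates_per_molecule, int):
        dups = np.full(sim.n_molecules, sim.duplicates_per_molecule)
    else:
        low, high = sim.duplicates_per_molecule
        dups = rng.integers(low, high + 1, size=sim.n_molecules)

    reads: list = []
    truth: list[TruthRecord] = []
    for mol in range(sim.n_molecules):
        umi = umis[mol]
        insert = _random_seq(rng, sim.insert_length)
        insert2 = _random_seq(rng, sim.insert_length) if sim.paired else None
        truth.append(TruthRecord(mol, umi, insert, insert2, int(dups[mol])))
        for dup in range(int(dups[mol])):
            rid = f"mol{mol}_dup{dup}"
            if sim.dual_umi:
                u1_obs, u1_q = _mutate(
                    rng, umi[: sim.umi_length], sim.umi_error_rate,
                    sim.quality_high, sim.quality_low,
                )
                u2_obs, u2_q = _mutate(
                    rng, umi[sim.umi_length :], sim.umi_error_rate,
                    sim.quality_high, sim.quality_low,
                )
            else:
                u1_obs, u1_q = _mutate(
                    rng, umi, sim.umi_error_rate, sim.quality_high, sim.quality_low
                )
            i1_obs, i1_q = _mutate(
                rng, insert, sim.insert_error_rate, sim.quality_high, sim.quality_low
            )
            r1 = ReadRecord(rid, u1_obs + i1_obs, u1_q + i1_q)
            if sim.paired:
                assert insert2 is not None
                i2_obs, i2_q = _mutate(
                    rng, insert2, sim.insert_error_rate,
                    sim.quality_high, sim.quality_low,
                )
                if sim.dual_umi:
                    r2 = ReadRecord(rid, u2_obs + i2_obs, u2_q + i2_q)
                else:
                    r2 = ReadRecord(rid, i2_obs, i2_q)
                reads.append(ReadPair(r1, r2))
            else:
                reads.append(r1)
    return reads, truth


def simulate_library(
    sim: SimConfig, out_dir: str | Path, sample_name: str = "sim"
) -> tuple[list[Path], Path]:
    """Write the simulated library as FASTQ plus a truth-table CSV.

    Returns (fastq paths, truth csv path). Paired libraries produce
    ``<sample>_R1.fastq`` / ``<sample>_R2.fastq``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, truth = simulate_reads(sim)

    fastq_paths: list[Path] = []
    if sim.paired:
        p1 = out_dir / f"{sample_name}_R1.fastq"
        p2 = out_dir / f"{sample_name}_R2.fastq"
        write_fastq((rp.r1 for rp in reads), p1)  # type: ignore[union-attr]
        write_fastq((rp.r2 for rp in reads), p2)  # type: ignore[union-attr]
        fastq_paths += [p1, p2]
    else:
        p1 = out_dir / f"{sample_name}_R1.fastq"
        write_fastq(iter(reads), p1)
        fastq_paths.append(p1)

    truth_path = out_dir / f"{sample_name}_truth.csv"
    pd.DataFrame(
        [
            {
                "molecule_id": t.molecule_id,
                "true_umi": t.true_umi,
                "true_insert": t.true_insert,
                "true_insert_r2": t.true_insert_r2 or "",
                "n_duplicates": t.n_duplicates,
            }
            for t in truth
        ]
    ).to_csv(truth_path, index=False)
    return fastq_paths, truth_path
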