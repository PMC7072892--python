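"""Synthetic paired array/sequencing datasets with planted ground truth.

The generator emulates the data regime the scoring method targets: a miRNA
microarray expression table (log2-like RMA-scale intensities) over a few
dozen samples, a matching precursor-probe table, miRBase-style annotation,
and a sequencing reference profile (median RPM). A planted subset of miRNAs
is "truly expressed": they carry low (early) MIMAT accession numbers, their
precursor profiles are rank-correlated with the mature profiles through a
shared latent signal, and their reference RPM is positive. The remaining
miRNAs are planted false positives: high MIMAT numbers, uncorrelated
precursors, zero reference RPM, GC-rich mature sequences, and multiple
near-match (<= 2 substitutions) copies planted in the synthetic genome.
Crucially, both groups draw their array intensities from the same high
range, so raw expression alone cannot separate them — scoring has to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnnotationSet,
    MirnaAnnotation,
    format_mimat,
    write_expression_table,
)

GENOME_ID = "synthetic_chr1"

_BASES = np.array(list("ACGT"))


def _pearson_for_spearman(s: float) -> float:
    """Pearson rho of a bivariate normal whose population Spearman is s."""
    return 2.0 * math.sin(math.pi * s / 6.0)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults mirror the regime the method was designed for: 30 samples,
    truly expressed miRNAs concentrated at MIMAT numbers below 5000 with
    precursor Spearman correlation near 0.8, false positives spread over
    high MIMAT numbers with GC-content elevated from 0.45 to 0.60.
    """

    n_true: int = 50
    n_false: int = 150
    n_samples: int = 30
    mimat_true_range: tuple[int, int] = (1, 5000)
    mimat_false_range: tuple[int, int] = (5001, 35000)
    corr_true: float = 0.8
    corr_false: float = 0.0
    gc_true_mean: float = 0.45
    gc_false_mean: float = 0.60
    noise_sd: float = 1.0
    seed: int = 0
    seq_length: int = 22
    false_genome_copies: int = 4
    # array intensities: log2-like base range covering moderate to high signal
    base_low: float = 6.0
    base_high: float = 13.0
    precursor_base_low: float = 4.0
    precursor_base_high: float = 9.0
    # reference RPM for true miRNAs: log-normal, median exp(rpm_log_mean)
    rpm_log_mean: float = math.log(100.0)
    rpm_log_sd: float = 1.2

    def __post_init__(self) -> None:
        if min(self.n_true, self.n_false, self.n_samples) < 1:
            raise ValueError("counts must be positive")
        for lo, hi, n in (
            (*self.mimat_true_range, self.n_true),
            (*self.mimat_false_range, self.n_false),
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"bad MIMAT range ({lo}, {hi})")
            if hi - lo + 1 < n:
                raise ValueError(
                    f"MIMAT range ({lo}, {hi}) too small for {n} miRNAs"
                )
        t, f = self.mimat_true_range, self.mimat_false_range
        if max(t[0], f[0]) <= min(t[1], f[1]):
            raise ValueError("true and false MIMAT ranges must be disjoint")
        for corr in (self.corr_true, self.corr_false):
            if not -1.0 <= corr <= 1.0:
                raise ValueError("correlation targets must lie in [-1, 1]")
        for gc in (self.gc_true_mean, self.gc_false_mean):
            if not 0.0 < gc < 1.0:
                raise ValueError("GC means must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.seq_length < 16:
            raise ValueError("seq_length must be >= 16 (mature miRNA scale)")


@dataclass
class SyntheticDataset:
    """A generated study: expression tables, annotation, reference, genome, truth."""

    mirna_matrix: pd.DataFrame
    precursor_matrix: pd.DataFrame
    annotation: AnnotationSet
    reference: pd.Series
    truth: dict[str, bool]
    genome: str
    genome_id: str = GENOME_ID
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _mutate(rng: np.random.Generator, seq: str, max_subs: int) -> str:
    n_subs = int(rng.integers(0, max_subs + 1))
    bases = list(seq)
    for pos in rng.choice(len(bases), size=n_subs, replace=False):
        alternatives = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(bases)


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a deterministic synthetic dataset for a given config/seed.

    Mature/precursor correlation is induced by a shared standard-normal
    latent signal per miRNA: with mixing coefficient rho chosen as
    ``2*sin(pi*s/6)`` (the bivariate-normal Spearman-to-Pearson identity),
    the population Spearman correlation equals the configured target ``s``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_true + config.n_false
    samples = [f"sample_{j + 1:02d}" for j in range(config.n_samples)]

    mature_names = [f"syn-miR-{i + 1:04d}-5p" for i in range(n_total)]
    precursor_names = [f"syn-mir-{i + 1:04d}" for i in range(n_total)]
    is_true = np.array([True] * config.n_true + [False] * config.n_false)

    mimat_true = rng.choice(
        np.arange(config.mimat_true_range[0], config.mimat_true_range[1] + 1),
        size=config.n_true,
        replace=False,
    )
    mimat_false = rng.choice(
        np.arange(config.mimat_false_range[0], config.mimat_false_range[1] + 1),
        size=config.n_false,
        replace=False,
    )
    mimats = np.concatenate([mimat_true, mimat_false])

    base = rng.uniform(config.base_low, config.base_high, size=n_total)
    pbase = rng.uniform(
        config.precursor_base_low, config.precursor_base_high, size=n_total
    )
    mirna_values = np.empty((n_total, config.n_samples))
    precursor_values = np.empty((n_total, config.n_samples))
    for i in range(n_total):
        target = config.corr_true if is_true[i] else config.corr_false
        rho = _pearson_for_spearman(target)
        z = rng.standard_normal(config.n_samples)
        w = rng.standard_normal(config.n_samples)
        mirna_values[i] = base[i] + config.noise_sd * z
        precursor_values[i] = pbase[i] + config.noise_sd * (
            rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * w
        )
    mirna_values = np.maximum(mirna_values, 0.0)
    precursor_values = np.maximum(precursor_values, 0.0)

    rpm = np.where(
        is_true,
        rng.lognormal(config.rpm_log_mean, config.rpm_log_sd, size=n_total),
        0.0,
    )

    sequences = [
        _random_sequence(
            rng,
            config.seq_length,
            config.gc_true_mean if is_true[i] else config.gc_false_mean,
        )
        for i in range(n_total)
    ]

    # genome: background chunks with each true sequence planted once and each
    # false sequence planted in several near-exact (<= 2 substitutions) copies
    plants: list[str] = []
    for i in range(n_total):
        copies = 1 if is_true[i] else config.false_genome_copies
        for _ in range(copies):
            plants.append(_mutate(rng, sequences[i], 0 if is_true[i] else 2))
    order = rng.permutation(len(plants))
    chunks: list[str] = []
    for idx in order:
        chunks.append(_random_sequence(rng, int(rng.integers(40, 120)), 0.40))
        chunks.append(plants[idx])
    chunks.append(_random_sequence(rng, int(rng.integers(40, 120)), 0.40))
    genome = "".join(chunks)

    records = {
        mature_names[i]: MirnaAnnotation(
            mature_name=mature_names[i],
            mimat_number=int(mimats[i]),
            precursor_names=(precursor_names[i],),
            sequence=sequences[i],
        )
        for i in range(n_total)
    }

    return SyntheticDataset(
        mirna_matrix=pd.DataFrame(
            mirna_values, index=mature_names, columns=samples
        ).rename_axis("name"),
        precursor_matrix=pd.DataFrame(
            precursor_values, index=precursor_names, columns=samples
        ).rename_axis("name"),
        annotation=AnnotationSet(records=records),
        reference=pd.Series(rpm, index=mature_names, name="median_rpm").rename_axis("name"),
        truth={mature_names[i]: bool(is_true[i]) for i in range(n_total)},
        genome=genome,
        config=config,
    )


#: filenames emitted by write_fixture
FIXTURE_FILES = (
    "mirna_expression.tsv",
    "precursor_expression.tsv",
    "aliases.txt",
    "mapping.tsv",
    "mature.fasta",
    "genome.fasta",
    "reference.tsv",
)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Write the dataset as the plain-text files the other modules read.

    Emits expression TSVs, miRBase-dialect aliases and precursor-to-mature
    mapping, mature and genome FASTA, and a reference TSV that carries the
    planted truth as an extra ``truly_expressed`` column (readers of the
    reference profile use the ``median_rpm`` column and ignore the rest).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression_table(dataset.mirna_matrix, directory / "mirna_expression.tsv")
    write_expression_table(
        dataset.precursor_matrix, directory / "precursor_expression.tsv"
    )
    records = dataset.annotation.records
    with open(directory / "aliases.txt", "w") as handle:
        for name in records:
            handle.write(f"{format_mimat(records[name].mimat_number)}\t{name};\n")
    with open(directory / "mapping.tsv", "w") as handle:
        for name in records:
            for precursor in records[name].precursor_names:
                handle.write(f"{precursor}\t{name}\n")
    with open(directory / "mature.fasta", "w") as handle:
        for name in records:
            handle.write(f">{name}\n{records[name].sequence}\n")
    with open(directory / "genome.fasta", "w") as handle:
        handle.write(f">{dataset.genome_id}\n")
        for start in range(0, len(dataset.genome), 70):
            handle.write(dataset.genome[start : start + 70] + "\n")
    table = pd.DataFrame(
        {
            "median_rpm": dataset.reference,
            "truly_expressed": [
                int(dataset.truth[name]) for name in dataset.reference.index
            ],
        }
    ).rename_axis("name")
    table.to_csv(directory / "reference.tsv", sep="\t")
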