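"""Synthetic data with known ground truth.

Generates the three kinds of inputs the downstream analyses consume, shaped
after the study design they emulate:

* **Count matrices** — negative-binomial gene x sample counts for five
  strains (two parents, two single deletions, the double deletion) at three
  timepoints (T0 before CaCl2, T45 and Tend after) across independent
  replicate batches, with a shared CaCl2 response, batch effects, library
  depth spread, planted strain-specific deviations and planted synergy
  genes (double-deletion effect beyond the product of the singles).
* **Plate growth curves** — logistic OD600 trajectories sampled every 15
  minutes with multiplicative log-normal noise.
* **3'UTR sequences** — random-background RNA with UAAU tetramers written
  at planted positions.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``: the expression generator draws four
child streams (parameters, batch effects, depths, counts) in that order, so
identical seeds and designs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .growth import GrowthCurve

__all__ = [
    "ExpressionDesign",
    "GrowthDesign",
    "simulate_counts",
    "simulate_plate",
    "simulate_utrs",
    "write_expression_files",
    "write_plate_csv",
    "write_utr_fasta",
]

DEFAULT_STRAINS = ("WT-a", "WT-alpha", "puf1D", "puf2D", "puf1Dpuf2D")
DEFAULT_PARENTS = {"puf1D": "WT-alpha", "puf2D": "WT-a", "puf1Dpuf2D": "WT-alpha"}
DEFAULT_DOUBLE = ("puf1Dpuf2D", "puf1D", "puf2D")
TIMEPOINTS = ("T0", "T45", "Tend")


@dataclass
class ExpressionDesign:
    """Design of a synthetic RNA-seq experiment.

    Per-gene parameters left as None are drawn once from the design's seed:
    baseline log2 mean counts from N(7, 2^2) and a shared CaCl2 log2
    response from N(0, 1) per stressed timepoint.  ``dispersion`` is the
    negative-binomial dispersion d in var = m + d*m^2 (scalar or per gene).
    ``planted_deviations`` maps (strain, timepoint) to {gene index: log2
    shift}; ``planted_synergy`` maps gene index to the extra log2 shift
    applied only in the double deletion (on top of the sum of the single
    deletions' effects) at stressed timepoints.
    """

    n_genes: int = 5034
    strains: tuple = DEFAULT_STRAINS
    parents: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PARENTS))
    double: tuple = DEFAULT_DOUBLE  # (double strain, single 1, single 2)
    timepoints: tuple = TIMEPOINTS
    n_replicates: int = 3
    baseline_log2_mean: np.ndarray | None = None
    dispersion: float | np.ndarray = 0.05
    batch_sd: float = 0.15
    libsize_sd: float = 0.25
    shared_response: Mapping[str, np.ndarray] | np.ndarray | None = None
    planted_deviations: Mapping[tuple, Mapping[int, float]] = field(default_factory=dict)
    planted_synergy: Mapping[int, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes: must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates: must be >= 2")
        if self.batch_sd < 0:
            raise ValueError("batch_sd: must be >= 0")
        if self.libsize_sd < 0:
            raise ValueError("libsize_sd: must be >= 0")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersion: all values must be > 0")
        if len(self.strains) < 5:
            raise ValueError("strains: need two parental and three deletion strains")
        for child, parent in self.parents.items():
            if child not in self.strains or parent not in self.strains:
                raise ValueError(f"parents: unknown strain in {child} -> {parent}")
        if any(s not in self.strains for s in self.double):
            raise ValueError("double: strains must appear in the strain list")
        for (strain, tp), genes in self.planted_deviations.items():
            if strain not in self.strains:
                raise ValueError(f"planted_deviations: unknown strain {strain!r}")
            if tp not in self.timepoints:
                raise ValueError(f"planted_deviations: unknown timepoint {tp!r}")
            if any(not 0 <= g < self.n_genes for g in genes):
                raise ValueError("planted_deviations: gene index out of range")
        if any(not 0 <= g < self.n_genes for g in self.planted_synergy):
            raise ValueError("planted_synergy: gene index out of range")


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def simulate_counts(design: ExpressionDesign) -> tuple[CountMatrix, dict[str, pd.DataFrame]]:
    """Draw a negative-binomial count matrix with its ground-truth tables.

    The log2 mean of gene g in sample (strain s, timepoint t, batch r) is

        baseline_g + shared_t,g [t != T0] + deviation_{s,t}(g)
        + batch_shift_r + log2 depth_{s,t,r}

    where the double-deletion strain's deviation is the sum of the two
    single deletions' planted deviations plus the planted synergy shift.
    Counts are NB with variance m + d*m^2.  Returns the CountMatrix and
    truth tables ``deviations`` (strain, timepoint, gene_id, log2_shift)
    and ``synergy`` (gene_id, extra_log2_shift).
    """
    design.validate()
    ss = np.random.SeedSequence(design.seed)
    rng_params, rng_batch, rng_depth, rng_counts = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    G = design.n_genes
    gene_ids = _gene_ids(G)
    baseline = (
        np.asarray(design.baseline_log2_mean, dtype=float)
        if design.baseline_log2_mean is not None
        else rng_params.normal(7.0, 2.0, size=G)
    )
    if baseline.shape != (G,):
        raise ValueError("baseline_log2_mean: need one value per gene")
    disp = np.broadcast_to(np.asarray(design.dispersion, dtype=float), (G,)).copy()

    stressed = [t for t in design.timepoints if t != "T0"]
    if design.shared_response is None:
        shared = {t: rng_params.normal(0.0, 1.0, size=G) for t in stressed}
    elif isinstance(design.shared_response, Mapping):
        shared = {t: np.asarray(design.shared_response[t], dtype=float) for t in stressed}
    else:
        arr = np.asarray(design.shared_response, dtype=float)
        shared = {t: arr for t in stressed}
    for t, arr in shared.items():
        if arr.shape != (G,):
            raise ValueError(f"shared_response[{t}]: need one value per gene")

    batches = [f"R{r + 1}" for r in range(design.n_replicates)]
    batch_shift = dict(zip(batches, rng_batch.normal(0.0, design.batch_sd, len(batches))))

    double_strain, single1, single2 = design.double

    def deviation_vector(strain: str, tp: str) -> np.ndarray:
        dev = np.zeros(G)
        for g, shift in design.planted_deviations.get((strain, tp), {}).items():
            dev[g] += shift
        if strain == double_strain:
            for s in (single1, single2):
                for g, shift in design.planted_deviations.get((s, tp), {}).items():
                    dev[g] += shift
            if tp != "T0":
                for g, extra in design.planted_synergy.items():
                    dev[g] += extra
        return dev

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for strain in design.strains:
        for tp in design.timepoints:
            dev = deviation_vector(strain, tp)
            log2_mu = baseline + (shared[tp] if tp != "T0" else 0.0) + dev
            for batch in batches:
                depth = 2.0 ** rng_depth.normal(0.0, design.libsize_sd)
                m = 2.0 ** (log2_mu + batch_shift[batch]) * depth
                r = 1.0 / disp  # NB size; var = m + d*m^2
                p = r / (r + m)
                sample_id = f"{strain}_{tp}_{batch}"
                columns[sample_id] = rng_counts.negative_binomial(r, p)
                meta_rows.append(dict(sample_id=sample_id, strain=strain,
                                      timepoint=tp, replicate_batch=batch))

    counts = pd.DataFrame(columns, index=gene_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    dev_rows = [
        dict(strain=strain, timepoint=tp, gene_id=gene_ids[g], log2_shift=shift)
        for (strain, tp), genes in sorted(design.planted_deviations.items())
        for g, shift in sorted(genes.items())
    ]
    syn_rows = [
        dict(gene_id=gene_ids[g], extra_log2_shift=extra)
        for g, extra in sorted(design.planted_synergy.items())
    ]
    truth = {
        "deviations": pd.DataFrame(dev_rows, columns=["strain", "timepoint", "gene_id", "log2_shift"]),
        "synergy": pd.DataFrame(syn_rows, columns=["gene_id", "extra_log2_shift"]),
    }
    return CountMatrix(counts=counts, samples=samples), truth


@dataclass
class GrowthDesign:
    """Logistic growth-curve design for one well.

    OD(t) = K*od0*e^{mu(t-lag)} / (K + od0*(e^{mu(t-lag)} - 1)) for t > lag
    and od0 before, times a log-normal noise factor with coefficient of
    variation ``noise_cv`` (mean 1).  Times are sampled every
    ``sampling_interval_min`` minutes for ``duration_hours`` hours.
    """

    od0: float = 0.05
    capacity: float = 1.2
    mu_per_hour: float = 0.5
    lag_hours: float = 1.0
    noise_cv: float = 0.02
    sampling_interval_min: int = 15
    duration_hours: float = 16.0
    strain: str = "sim"
    condition: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if self.od0 <= 0:
            raise ValueError("od0: must be > 0")
        if self.capacity <= self.od0:
            raise ValueError("capacity: must exceed od0")
        if self.mu_per_hour <= 0:
            raise ValueError("mu_per_hour: must be > 0")
        if self.lag_hours < 0:
            raise ValueError("lag_hours: must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv: must be >= 0")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min: must be > 0")

    def closed_form(self, t_hours: np.ndarray) -> np.ndarray:
        """Noise-free logistic OD at times given in hours."""
        t = np.asarray(t_hours, dtype=float)
        dt = np.maximum(t - self.lag_hours, 0.0)
        growth = np.exp(self.mu_per_hour * dt)
        return self.capacity * self.od0 * growth / (
            self.capacity + self.od0 * (growth - 1.0)
        )


def simulate_plate(designs: Mapping[str, GrowthDesign]) -> list[GrowthCurve]:
    """Simulate one GrowthCurve per well from its GrowthDesign."""
    if not designs:
        raise ValueError("need at least one well")
    curves = []
    for well, d in sorted(designs.items()):
        d.validate()
        rng = np.random.default_rng(np.random.SeedSequence(d.seed))
        n = int(d.duration_hours * 60 / d.sampling_interval_min) + 1
        times = np.arange(n, dtype=float) * d.sampling_interval_min
        od = d.closed_form(times / 60.0)
        if d.noise_cv > 0:
            sigma = np.sqrt(np.log1p(d.noise_cv**2))
            od = od * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n))
        curves.append(GrowthCurve(well_id=well, strain=d.strain,
                                  condition=d.condition, times=times, od=od))
    return curves


def simulate_utrs(
    n_seqs: int,
    length_range: tuple[int, int] = (80, 300),
    planted: Mapping[str | int, Sequence[int]] | None = None,
    seed: int = 0,
    linker_range: tuple[int, int] = (1, 8),
) -> tuple[dict[str, str], dict[str, pd.DataFrame]]:
    """Random-background RNA sequences with UAAU motifs written at planted
    positions.

    ``planted`` maps a sequence id (or integer index) to motif start
    positions.  Returns the sequences and truth tables: ``singles``
    (seq_id, position) for every planted motif and ``duals`` (seq_id, pos1,
    pos2) for every planted pair of consecutive motifs whose linker falls
    in ``linker_range``.  Placements that run past the sequence end, or
    overlap with conflicting letters, are rejected.
    """
    if n_seqs < 1:
        raise ValueError("n_seqs: must be >= 1")
    lo, hi = length_range
    if not 4 <= lo <= hi:
        raise ValueError("length_range: need 4 <= min <= max")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids = [f"utr{i:04d}" for i in range(n_seqs)]
    planted = planted or {}
    planted_by_id: dict[str, list[int]] = {}
    for key, positions in planted.items():
        sid = ids[key] if isinstance(key, int) else key
        if sid not in ids:
            raise KeyError(f"unknown sequence id {sid!r}")
        planted_by_id[sid] = sorted(positions)

    alphabet = np.array(list("ACGU"))
    motif = "UAAU"
    seqs: dict[str, str] = {}
    single_rows, dual_rows = [], []
    for sid in ids:
        length = int(rng.integers(lo, hi + 1))
        chars = alphabet[rng.integers(0, 4, size=length)]
        fixed = np.zeros(length, dtype=bool)
        for pos in planted_by_id.get(sid, []):
            if pos < 0 or pos + len(motif) > length:
                raise ValueError(f"{sid}: placement at {pos} outside sequence of length {length}")
            for i, letter in enumerate(motif):
                if fixed[pos + i] and chars[pos + i] != letter:
                    raise ValueError(f"{sid}: overlapping incompatible placements at {pos}")
                chars[pos + i] = letter
                fixed[pos + i] = True
            single_rows.append(dict(seq_id=sid, position=pos))
        pos_list = planted_by_id.get(sid, [])
        for p1, p2 in zip(pos_list, pos_list[1:]):
            linker = p2 - (p1 + len(motif))
            if linker_range[0] <= linker <= linker_range[1]:
                dual_rows.append(dict(seq_id=sid, pos1=p1, pos2=p2))
        seqs[sid] = "".join(chars)

    truth = {
        "singles": pd.DataFrame(single_rows, columns=["seq_id", "position"]),
        "duals": pd.DataFrame(dual_rows, columns=["seq_id", "pos1", "pos2"]),
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# writers (plain-text formats)

def write_expression_files(m: CountMatrix, truth: dict[str, pd.DataFrame], outdir) -> None:
    """Write counts TSV, sample metadata TSV and truth TSVs into a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    m.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    m.samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    for name, df in truth.items():
        df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


def write_plate_csv(curves: Sequence[GrowthCurve], path) -> None:
    """Write growth curves as a long-format CSV (well, time_min, od)."""
    rows = [
        dict(well=c.well_id, time_min=t, od=o)
        for c in curves
        for t, o in zip(c.times, c.od)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_utr_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
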