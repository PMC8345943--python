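"""Composed in-silico experiments: frequency sweeps and block substitutions.

The experiment layer turns a configuration (sequence source, edits, drive
ladder, integration settings) into batches of runs and comparison reports:

* the ω-sweep over the drive ladder
  {10¹¹, 5·10¹⁰, 10¹⁰, 5·10⁹, 10⁹, 10⁸, 0} s⁻¹ at F₀ = 0.5·10⁻²² J, with
  the ω = 0 (constant force) run always serving as the reference when
  frequency independence is assessed;
* the homopolymer-substitution battery (40A/40T/40G/40C, and 100A) in a
  centered block of the chain-1 sequence at fixed ω, with a pairwise
  amplitude-ratio matrix and an estimator-sensitivity table;
* report files: TSV summary tables, ratio matrices, and offset plots of
  the chain-mean angular deviations.

Everything is deterministic: a configuration fully determines every output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, sequence_io
from .analysis import RunSummary, summarize
from .integration import IntegrationSettings, Trajectory, integrate
from .model import AS_PRINTED, build_system
from .params import ForceSpec, ParamTable
from .sequence_io import NucleotideSequence

log = logging.getLogger("dnatorsion")

#: Drive angular-frequency ladder of the sweep experiment, s^-1.
OMEGA_LADDER = (1e11, 5e10, 1e10, 5e9, 1e9, 1e8, 0.0)
#: Default drive amplitude, J.
F0_DEFAULT = 0.5e-22
#: Default drive frequency of the substitution battery, s^-1.
OMEGA_SUBSTITUTION = 1e8


@dataclass(frozen=True)
class SyntheticSpec:
    """Synthetic-sequence source: heterogeneous n-mer with given GC content."""

    n: int = 980
    gc_fraction: float = 0.5
    seed: int = 1


@dataclass(frozen=True)
class EditSpec:
    """One substitute_region edit: ``length`` copies of ``base`` at ``start`` (1-based)."""

    start: int
    length: int
    base: str

    @property
    def label(self) -> str:
        return f"{self.length}{self.base}"


@dataclass
class ExperimentConfig:
    """Everything that determines an experiment batch."""

    fasta: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    edits: list = field(default_factory=list)
    omegas: tuple = OMEGA_LADDER
    F0: float = F0_DEFAULT
    variant: str = AS_PRINTED
    settings: IntegrationSettings = field(default_factory=lambda: IntegrationSettings(store_states=False))
    transient_cutoff: float = analysis.TRANSIENT_CUTOFF_DEFAULT
    amplitude_method: str = "half_range"
    outdir: str | None = None
    param_table: ParamTable = field(default_factory=ParamTable.default)

    def load_sequence(self) -> NucleotideSequence:
        if self.fasta is not None:
            return sequence_io.read_fasta(self.fasta)
        s = self.synthetic
        return sequence_io.random_sequence(s.n, s.gc_fraction, s.seed)

    def to_yaml(self, path) -> None:
        doc = {
            "fasta": self.fasta,
            "synthetic": dataclasses.asdict(self.synthetic),
            "edits": [dataclasses.asdict(e) for e in self.edits],
            "omegas": list(self.omegas),
            "F0": self.F0,
            "variant": self.variant,
            "settings": {
                "dt": self.settings.dt,
                "t_end": self.settings.t_end,
                "record_stride": self.settings.record_stride,
                "store_states": self.settings.store_states,
            },
            "transient_cutoff": self.transient_cutoff,
            "amplitude_method": self.amplitude_method,
            "outdir": self.outdir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls()
        if doc.get("fasta") is not None:
            cfg.fasta = doc["fasta"]
        if "synthetic" in doc:
            cfg.synthetic = SyntheticSpec(**doc["synthetic"])
        cfg.edits = [EditSpec(**e) for e in doc.get("edits", [])]
        if "omegas" in doc:
            cfg.omegas = tuple(float(w) for w in doc["omegas"])
        cfg.F0 = float(doc.get("F0", cfg.F0))
        cfg.variant = doc.get("variant", cfg.variant)
        if "settings" in doc:
            s = doc["settings"]
            cfg.settings = IntegrationSettings(
                dt=float(s.get("dt", 1e-14)),
                t_end=float(s.get("t_end", 5e-9)),
                record_stride=s.get("record_stride"),
                store_states=bool(s.get("store_states", False)),
            )
        cfg.transient_cutoff = float(doc.get("transient_cutoff", cfg.transient_cutoff))
        cfg.amplitude_method = doc.get("amplitude_method", cfg.amplitude_method)
        cfg.outdir = doc.get("outdir")
        return cfg


def desk_config(**overrides) -> ExperimentConfig:
    """Small, minutes-scale configuration: n = 100, t_end = 10⁻⁹ s."""
    cfg = ExperimentConfig(
        synthetic=SyntheticSpec(n=100, gc_fraction=0.5, seed=1),
        settings=IntegrationSettings(t_end=1e-9, store_states=False),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def gene_config(**overrides) -> ExperimentConfig:
    """Gene-scale configuration: n = 980, t_end = 5·10⁻⁹ s."""
    cfg = ExperimentConfig(
        synthetic=SyntheticSpec(n=980, gc_fraction=0.5, seed=1),
        settings=IntegrationSettings(t_end=5e-9, store_states=False),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def run_one(
    seq: NucleotideSequence,
    omega: float,
    config: ExperimentConfig,
) -> tuple[Trajectory, RunSummary]:
    """Simulate one (sequence, ω) condition and summarize it."""
    import time

    system = build_system(
        seq,
        params=config.param_table,
        force=ForceSpec(F0=config.F0, omega=omega),
        variant=config.variant,
    )
    t0 = time.perf_counter()
    traj = integrate(system, settings=config.settings)
    log.info(
        "run %s omega=%.3e: n=%d dt=%.1e t_end=%.1e digest=%s wall=%.1fs",
        seq.id, omega, system.n, config.settings.dt, config.settings.t_end,
        traj.metadata["sequence_sha256_16"], time.perf_counter() - t0,
    )
    summary = summarize(
        traj,
        chain=1,
        transient_cutoff=config.transient_cutoff,
        amplitude_method=config.amplitude_method,
    )
    summary.metadata["sequence_label"] = seq.id
    return traj, summary


def run_frequency_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """One run per ω of the ladder; reports deviation from the ω = 0 run.

    The returned table has one row per ω with the post-transient amplitude,
    the dominant frequency, and — when the ladder contains ω = 0 — the
    relative deviation of each dominant frequency from the constant-force
    run's, the internal reference for the frequency-independence claim.
    Failures of individual runs are recorded per-row rather than aborting
    the batch.
    """
    seq = config.load_sequence()
    rows = []
    summaries: dict[float, RunSummary] = {}
    for omega in config.omegas:
        try:
            _, summary = run_one(seq, omega, config)
            summaries[omega] = summary
            rows.append(
                {
                    "omega": omega,
                    "drive_frequency_hz": omega / (2.0 * np.pi),
                    "amplitude_rad": summary.amplitude,
                    "dominant_frequency_hz": summary.dominant_frequency,
                    "status": "ok",
                }
            )
            log.info(
                "sweep omega=%.3e: amplitude=%.3e rad, f_dom=%.3e Hz",
                omega, summary.amplitude, summary.dominant_frequency,
            )
        except Exception as err:  # keep partial results
            log.warning("sweep omega=%.3e failed: %s", omega, err)
            rows.append(
                {
                    "omega": omega,
                    "drive_frequency_hz": omega / (2.0 * np.pi),
                    "amplitude_rad": np.nan,
                    "dominant_frequency_hz": np.nan,
                    "status": f"error: {err}",
                }
            )
    df = pd.DataFrame(rows)
    if 0.0 in summaries:
        f_ref = summaries[0.0].dominant_frequency
        if f_ref > 0:
            df["rel_freq_deviation_from_omega0"] = (
                np.abs(df["dominant_frequency_hz"] - f_ref) / f_ref
            )
    df.attrs["sequence_label"] = seq.id
    return df


def substitution_variants(seq: NucleotideSequence, edits: list) -> dict[str, NucleotideSequence]:
    """The unedited sequence plus one edited sequence per EditSpec."""
    out = {"unedited": seq}
    for e in edits:
        out[e.label] = sequence_io.substitute_region(seq, e.start, e.length, e.base)
    return out


def default_edits(n: int) -> list:
    """The centered 40A/40T/40G/40C and 100A blocks for an n-mer."""
    s40 = sequence_io.centered_block(n, 40)
    s100 = sequence_io.centered_block(n, 100)
    return [
        EditSpec(s40, 40, "A"),
        EditSpec(s40, 40, "T"),
        EditSpec(s40, 40, "G"),
        EditSpec(s40, 40, "C"),
        EditSpec(s100, 100, "A"),
    ]


def run_substitution_experiment(
    config: ExperimentConfig, omega: float = OMEGA_SUBSTITUTION
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the unedited sequence and every edited variant at fixed ω.

    Returns (summary table, pairwise amplitude-ratio matrix).  The summary
    table includes amplitudes under every available estimator so that any
    ratio claim can be checked for sensitivity to the estimator choice; the
    ratio matrix uses the configured default estimator.  Variants are also
    ranked by amplitude.
    """
    seq = config.load_sequence()
    edits = config.edits if config.edits else default_edits(len(seq))
    variants = substitution_variants(seq, edits)
    rows = []
    amps: dict[str, float] = {}
    for label, vseq in variants.items():
        traj, summary = run_one(vseq, omega, config)
        series = analysis.mean_angular_deviation(
            traj, chain=1, transient_cutoff=config.transient_cutoff
        )
        row = {
            "variant": label,
            "omega": omega,
            "amplitude_rad": summary.amplitude,
            "dominant_frequency_hz": summary.dominant_frequency,
        }
        for method in analysis.AMPLITUDE_METHODS:
            row[f"amplitude_{method}"] = analysis.amplitude(series, method=method)
        rows.append(row)
        amps[label] = summary.amplitude
    df = pd.DataFrame(rows)
    df["rank_by_amplitude"] = df["amplitude_rad"].rank(ascending=False).astype(int)
    labels = list(variants)
    ratio = pd.DataFrame(
        [[amps[a] / amps[b] if amps[b] != 0 else np.nan for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    df.attrs["sequence_label"] = seq.id
    return df, ratio


def generate_report(
    summaries: pd.DataFrame,
    out: str | Path,
    ratio_matrix: pd.DataFrame | None = None,
    trajectories: dict[str, Trajectory] | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write the summary table (TSV), ratio matrix and optional offset plot.

    Plots stack the chain-mean angular deviation curves with vertical
    offsets, one curve per run, as trajectory figures conventionally do.
    Returns the list of files written.
    """
    if len(summaries) < 1:
        raise ValueError("need at least one run summary")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    table_path = out / "summaries.tsv"
    summaries.to_csv(table_path, sep="\t", index=False, float_format="%.10g")
    written.append(table_path)
    if ratio_matrix is not None and len(summaries) > 1:
        ratio_path = out / "amplitude_ratios.tsv"
        ratio_matrix.to_csv(ratio_path, sep="\t", float_format="%.10g")
        written.append(ratio_path)
    if plot and trajectories:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 1.2 * len(trajectories) + 2))
        offset = 0.0
        for label, traj in trajectories.items():
            span = np.ptp(traj.mean1)
            ax.plot(traj.times * 1e9, traj.mean1 + offset, lw=0.7, label=label)
            offset += 1.2 * span if span > 0 else 1.0
        ax.set_xlabel("t, ns")
        ax.set_ylabel("mean angular deviation of chain 1 (offset), rad")
        ax.legend(fontsize="small")
        plot_path = out / "mean_deviation_offsets.png"
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        written.append(plot_path)
    return written
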