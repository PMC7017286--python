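"""Run configuration: per-mark detector parameters, QC thresholds, simulator.

Defaults reproduce the study's software-parameter table (per-mark FDR
0.05/0.01/0.01/0.1, fragment size 200, SICER window 200 and gap 4, genome
fraction 0.63, effective genome size 2,409,143,234) and the QC threshold
row (NRF>0.5, PBC1>0.5, PBC2>1, NSC>1.05, RSC>0.8, JSD>0.05) exactly when
untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .peaks import MarkConfig, default_mark_configs
from .readqc import QCThresholds
from .simdata import SimConfig


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    marks: dict[str, MarkConfig] = field(default_factory=default_mark_configs)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    outdir: Path = Path("equichip_run")
    seed: int = 0
    replicates: int = 2
    jsd_bin_size: int = 500
    xcor_max_shift: int = 500
    track_bin_size: int = 50
    flank_bp: int = 3000
    body_bins: int = 100
    motif_alpha: float = 0.05
    n_decoy_motifs: int = 8
    log_level: str = "INFO"

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.seed != self.sim.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.sim)
        sim["chrom_lengths"] = dict(sim["chrom_lengths"])
        if not isinstance(sim["motif_consensus"], str):
            sim["motif_consensus"] = dict(sim["motif_consensus"])
        sim["marks"] = list(sim["marks"])
        sim["gene_length_range"] = list(sim["gene_length_range"])
        return {
            "sim": sim,
            "marks": {m: dataclasses.asdict(c) for m, c in self.marks.items()},
            "thresholds": dataclasses.asdict(self.thresholds),
            "outdir": str(self.outdir),
            "seed": self.seed,
            "replicates": self.replicates,
            "jsd_bin_size": self.jsd_bin_size,
            "xcor_max_shift": self.xcor_max_shift,
            "track_bin_size": self.track_bin_size,
            "flank_bp": self.flank_bp,
            "body_bins": self.body_bins,
            "motif_alpha": self.motif_alpha,
            "n_decoy_motifs": self.n_decoy_motifs,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        try:
            if "sim" in kwargs:
                sim = dict(kwargs["sim"])
                if "gene_length_range" in sim:
                    sim["gene_length_range"] = tuple(sim["gene_length_range"])
                if "marks" in sim:
                    sim["marks"] = tuple(sim["marks"])
                kwargs["sim"] = SimConfig(**sim)
            if "marks" in kwargs:
                kwargs["marks"] = {m: MarkConfig(**c) for m, c in kwargs["marks"].items()}
            if "thresholds" in kwargs:
                kwargs["thresholds"] = QCThresholds(**kwargs["thresholds"])
        except TypeError as exc:
            raise ConfigurationError(f"invalid run configuration: {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def write_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def demo_run_config(outdir="results/demo", seed: int = 1) -> RunConfig:
    """A small full-cohort demo: 3 tissues x 4 marks x 2 replicates, 1.2 Mb genome."""
    sim = SimConfig(
        chrom_lengths={"chr1": 700_000, "chr2": 500_000},
        n_tissues=3,
        reads_per_library=60_000,
        n_shared_elements=24,
        n_specific_elements_per_tissue=8,
        # one distinct, reasonably specific consensus per tissue so the
        # unique-detection analysis has signal (short degenerate motifs such
        # as DAAAYA occur by chance in most 500 bp backgrounds)
        motif_consensus={"tissue_1": "WAWGTAAAYAW",
                         "tissue_2": "GCCCCKCCCCC",
                         "tissue_3": "YGCCCBVRGGCA"},
        seed=seed,
    )
    return RunConfig(sim=sim, outdir=Path(outdir), seed=seed)
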