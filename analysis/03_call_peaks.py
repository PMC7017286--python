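"""Per-replicate peak calling: narrow windows for H3K4me1/H3K4me3/H3K27ac,
broad SICER-style islands for H3K27me3, all against the matched input.
"""

from equichip import io
from equichip.config import demo_run_config
from equichip.pipeline import run_stage


def main():
    cfg = demo_run_config()
    run_stage("callpeaks", cfg)
    for path in sorted((cfg.outdir / "peaks").iterdir()):
        reader = io.read_broadpeak if path.suffix == ".broadPeak" else io.read_narrowpeak
        called = reader(path)
        print(f"{path.name}: {len(called)} regions of enrichment")


if __name__ == "__main__":
    main()
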