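"""Replicate consensus: overlapping regions of enrichment in both
biological replicates where at least one member passes the mark-specific
FDR threshold, merged to their union span.
"""

import pandas as pd

from equichip.config import demo_run_config
from equichip.pipeline import run_stage


def main():
    cfg = demo_run_config()
    run_stage("combine", cfg)
    summary = pd.read_csv(cfg.outdir / "consensus" / "consensus_summary.tsv", sep="\t")
    print(summary.to_string(index=False))
    total = summary["combined_peaks"].sum()
    print(f"\n{total} consensus peaks across "
          f"{summary[['tissue', 'mark']].drop_duplicates().shape[0]} tissue-mark pairs")


if __name__ == "__main__":
    main()
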