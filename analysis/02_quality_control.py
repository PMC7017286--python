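"""Six-metric QC panel for every ChIP library in the demo cohort.

Applies the strict alignment filters, computes library complexity (NRF,
PBC1, PBC2) on the pre-dedup tags, then strand cross-correlation (NSC,
RSC) and the ChIP-vs-input Jensen-Shannon distance on the deduplicated
tags, and scores each metric against the ENCODE/FAANG thresholds.
"""

import pandas as pd

from equichip.config import demo_run_config
from equichip.pipeline import run_stage


def main():
    cfg = demo_run_config()
    run_stage("qc", cfg)
    table = pd.read_csv(cfg.outdir / "qc" / "qc_report.tsv", sep="\t")
    metric_cols = ["NRF", "PBC1", "PBC2", "NSC", "RSC", "JSD"]
    print(table[["tissue", "mark", "replicate"] + metric_cols].to_string(index=False))
    n_fail = (~table[[c + "_pass" for c in metric_cols]]).sum().sum()
    print(f"\n{len(table)} libraries scored; {int(n_fail)} metric failures")


if __name__ == "__main__":
    main()
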