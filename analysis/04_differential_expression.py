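#!/usr/bin/env python
"""Differential expression between clonality-defined groups.

Three contrasts on the simulated cohort: singleton vs expanded
(Small-Large) cells, blood-enriched vs tissue-enriched cells, and
regulatory-cluster (C5) cells blood vs plaque.  Wilcoxon rank-sum,
Bonferroni over all genes, significance at p < 1e-6 with |log2FC| >=
0.5.  Writes one de_<contrast>.csv per contrast under results/analysis/
and prints the top significant genes.
"""

import logging
from pathlib import Path

from pairedtcr.pipeline import DEFAULT_CONTRASTS, stage_de
from pairedtcr.simulate import read_back_dataset

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    dataset = read_back_dataset(DATA)
    results = stage_de(dataset, DEFAULT_CONTRASTS, OUT)
    for name, table in results.items():
        sig = table[table["significant"]]
        print(f"\n{name}: {len(sig)} significant genes")
        for row in sig.head(8).itertuples(index=False):
            direction = "A" if row.log2fc > 0 else "B"
            print(f"  {row.gene:10s} p={row.p_value:.2e} log2fc={row.log2fc:+.2f} "
                  f"(higher in group {direction})")


if __name__ == "__main__":
    main()
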