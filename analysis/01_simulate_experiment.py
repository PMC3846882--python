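"""Generate the synthetic AP-MS experiment all later analyses run on.

Emulated design: a 12-member core complex with three overexpressed baits
(three biological replicates each), one mock-tag control run, one deep
whole-cell-lysate run, 200 background proteins of which ~30% bind stickily,
one planted non-reference candidate member (enrichment 0.5), and two
engineered isoform pairs. Writes FASTA/TSV fixtures under
scratch/fixtures/ (regenerable scratch data, not part of the results).
"""

import argparse
from pathlib import Path

from apmsref.pipeline import PipelineConfig, make_fixtures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()

    cfg = make_fixtures(PipelineConfig(seed=args.seed, outdir=str(args.scratch)))
    fixdir = Path(cfg.fasta).parent
    n_lines = sum(1 for line in open(cfg.fasta) if line.startswith(">"))
    print(f"wrote {fixdir}")
    print(f"  protein database: {n_lines} sequences "
          "(12 core incl. 3 baits, 1 candidate, 200 background, 2 isoform pairs)")
    with open(cfg.design) as fh:
        n_runs = sum(1 for _ in fh) - 1
    print(f"  design: {n_runs} runs (3 baits x 3 replicates + control + WCL)")
    print(f"  reference set: 12 core members (candidate deliberately excluded)")


if __name__ == "__main__":
    main()
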