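"""End-to-end run: simulate → filter → fill → LD → tag → summarize.

Every stage writes and reads standard formats (VCF/BED/TSV) in the run
directory, so any later stage can be re-run from disk.  Equivalent to
``svld run-all --out demo_run --seed 2`` on the command line.
"""

import json

from svld import RunConfig, SimConfig, run_all

index = run_all(SimConfig(seed=2), RunConfig(out_dir="demo_run", seed=2))

print(json.dumps({k: v for k, v in index.items() if k != "files"}, indent=2))
print("key outputs:")
for name in ("filter_report.tsv", "ld_decay.tsv", "relative_ld.tsv",
             "tagged_shares.tsv", "hwe.tsv"):
    print(f"  demo_run/{name}")

# results.json indexes all artifacts; ld_decay.tsv holds the binned decay
# curves per population and pair class, relative_ld.tsv the Table-style
# relative summaries, tagged_shares.tsv the tag-SNP shares per class.
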