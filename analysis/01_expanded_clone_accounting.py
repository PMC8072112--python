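#!/usr/bin/env python
"""Clonotype accounting of the expanded CLL/SLL clones.

Starting from the transcribed per-tissue clone observations, this script
collapses identical clones across tissues and allotransplanted F1
recipients, then reports: the canonical clone count, the unmutated/mutated
split, the stereotyped HCDR3 sets shared across mice, HCDR3 length/pI
summaries, and V-gene usage with proportion tests against the background
rearrangement frequencies of normal mouse strains (1.9% for VH7183.a47.76,
1.2% for VHJ558.b9, and <0.1% for VHSM7.a2psi.88).

Writes results/expanded_clones/*.tsv and a summary JSON.
"""

import json
from pathlib import Path

import pandas as pd

from ighrep.fixtures import load_expanded_clone_table
from ighrep.hcdr3 import (canonicalize_clones, compute_pi, detect_stereotypes,
                          mutation_status_summary)
from ighrep.pipeline import stereotype_frame
from ighrep.stats import frequency_table, proportion_test, summarize_features

OUT = Path("results/expanded_clones")
OUT.mkdir(parents=True, exist_ok=True)

BACKGROUND_PERCENT = {"VH7183.a47.76": 1.86, "VHJ558.b9": 1.18,
                      "VHSM7.a2psi.88": 0.1}

table = load_expanded_clone_table()
clones = canonicalize_clones(table)
expanded = [c for c in clones if c.is_expanded]
print(f"{len(table)} per-tissue observations -> {len(expanded)} canonical "
      "expanded clones")

pct_um, pct_m = mutation_status_summary(clones, expanded_only=True)
print(f"mutation status: {pct_um}% UM / {pct_m}% M")

sets, pct_stereo = detect_stereotypes(expanded)
stereotype_frame(sets).to_csv(OUT / "stereotypes.tsv", sep="\t", index=False)
for s in sets:
    print(f"stereotype {s.cdr3_aa}: {s.n_mice} mice")
print(f"stereotyped clones: {pct_stereo:.0f}% of the canonical set")

lengths = {c.cdr3_aa: float(len(c.cdr3_aa)) for c in expanded}
pis = {c.cdr3_aa: compute_pi(c.cdr3_aa) for c in expanded}
mean_len, sd_len, n = summarize_features(expanded, lengths, "length")
mean_pi, sd_pi, _ = summarize_features(expanded, pis, "pI")
print(f"HCDR3 length {mean_len} +/- {sd_len} AA; pI {mean_pi} +/- {sd_pi} "
      f"(n = {n})")

usage = frequency_table(expanded, level="gene", segment="V").reset_index()
usage.to_csv(OUT / "gene_usage.tsv", sep="\t", index=False)
rows = []
for gene, background in BACKGROUND_PERCENT.items():
    k = int(usage.loc[usage["category"] == gene, "all"].sum())
    res = proportion_test(k, n, background / 100.0)
    rows.append({"gene": gene, "k": k, "n": n, "background_percent": background,
                 "z": round(res.statistic, 2), "p": res.p_value})
    print(f"{gene}: {k}/{n} ({100 * k / n:.0f}%) vs {background}% background, "
          f"z = {res.statistic:.2f}, p = {res.p_value:.2g}")
pd.DataFrame(rows).to_csv(OUT / "proportion_tests.tsv", sep="\t", index=False)

summary = {"n_canonical_expanded": len(expanded), "percent_um": pct_um,
           "percent_m": pct_m, "stereotyped_percent": round(pct_stereo, 1),
           "mean_length": mean_len, "sd_length": sd_len,
           "mean_pi": mean_pi, "sd_pi": sd_pi}
(OUT / "summary.json").write_text(json.dumps(summary, indent=1))
print(f"wrote {OUT}/")
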