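#!/usr/bin/env python
"""Cohort statistics on the simulated counts: group x timepoint summary,
percent change from baseline, split-plot ANOVA and the normality check.
Reads results/cohort/cohort.csv (run 01 first) and writes to
results/stats/."""

from pathlib import Path

from hrdquant import io
from hrdquant.pipeline import compute_cohort_stats

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "stats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = io.read_cohort_csv(ROOT / "cohort" / "cohort.csv")
    res = compute_cohort_stats(cohort)
    res["summary"].to_csv(OUT / "summary.csv", index=False)
    res["percent_change"].to_csv(OUT / "percent_change.csv", index=False)
    io.write_json(res["anova"], OUT / "anova.json")
    anova = {r["effect"]: r for r in res["anova"]["between_within"]}
    inter = anova["group:time"]
    print(res["percent_change"].to_string(index=False))
    print(f"\ngroup x time interaction: F = {inter['F']:.2f}, p = {inter['p']:.2e} "
          f"(Greenhouse-Geisser p = {inter['p_gg']:.2e})")


if __name__ == "__main__":
    main()
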