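"""Survey-level statistics for the benchmark identification run.

Computes the headline mislabeling rate with its exact 95% CI, channel and
year breakdowns, and the comparison against the earlier pre-regulation
survey (which enters as published counts, 18/95 ~ 19%, never recomputed).
Writes results/survey_summary.{tsv,txt}.  Requires 03_run_identification.py
to have produced nothing -- it reruns the pipeline itself so it can be
executed standalone.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from caviarid.market_fixture import (FIXTURE_SURVEY_CONFIG,
                                     benchmark_reference_db,
                                     encode_benchmark_survey)
from caviarid.survey_stats import breakdown, compare_periods, mislabeling_rate
from caviarid.surveyio import summary_text
from caviarid.workflow import run_survey

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
BASELINE = (18, 95)  # earlier survey, published counts (~19%)


def main() -> None:
    db = benchmark_reference_db()
    lots, _ = encode_benchmark_survey(db)
    results = run_survey(lots, db, FIXTURE_SURVEY_CONFIG)
    summary = mislabeling_rate(results)
    by_channel = breakdown(results, "channel")
    by_year = breakdown(results, "year")
    comp = compare_periods((summary.n_mislabeled, summary.n_testable),
                           BASELINE)

    rows = [{"stratum": "overall", "n_testable": summary.n_testable,
             "n_mislabeled": summary.n_mislabeled,
             "rate_pct": summary.rate_percent,
             "ci_low_pct": summary.ci_low_percent,
             "ci_high_pct": summary.ci_high_percent}]
    for name, strata in (("channel", by_channel), ("year", by_year)):
        for value, s in strata.items():
            rows.append({"stratum": f"{name}={value}",
                         "n_testable": s.n_testable,
                         "n_mislabeled": s.n_mislabeled,
                         "rate_pct": s.rate_percent,
                         "ci_low_pct": s.ci_low_percent,
                         "ci_high_pct": s.ci_high_percent})
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "survey_summary.tsv", sep="\t",
                              index=False, float_format="%.2f")

    text = summary_text(summary, by_channel)
    text += ("\n\nvs earlier survey (input counts "
             f"{BASELINE[0]}/{BASELINE[1]}):\n"
             f"  rate difference:    {comp.difference_percent:+.1f} points\n"
             f"  95% CI (Newcombe):  [{comp.ci_low_percent:+.1f}, "
             f"{comp.ci_high_percent:+.1f}]\n"
             f"  Fisher exact p:     {comp.p_value:.3f}\n")
    (OUT / "survey_summary.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
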