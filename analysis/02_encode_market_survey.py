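"""Write the encoded 92-tin benchmark market survey to results/survey.

The survey reproduces a two-year (2006/2008) purchase campaign across nine
retail shops and a dozen online retailers: 92 tins spanning eight market
labels, two tins with no recoverable DNA, one pike substitute identifiable
only through cox1, and the D-loop amplification failures that restrict some
osetra lots to a cytb-only identification.
"""

import pathlib
import sys
from collections import Counter

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from caviarid.market_fixture import benchmark_reference_db, \
    encode_benchmark_survey
from caviarid.surveyio import write_survey

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    db = benchmark_reference_db()
    lots, expected = encode_benchmark_survey(db)
    write_survey(lots, OUT / "survey")
    print(f"wrote {len(lots)} lots -> {OUT / 'survey'}")
    by_market = Counter(lot.label.market for lot in lots)
    for market, n in by_market.most_common():
        print(f"  {market:<12} {n}")
    by_channel = Counter((lot.channel, lot.year) for lot in lots)
    for (channel, year), n in sorted(by_channel.items()):
        print(f"  {channel} {year}: {n}")
    print(f"expected: {expected.n_testable} testable, "
          f"{expected.n_mislabeled} mislabeled "
          f"({expected.mislabeling_rate_percent}%), "
          f"{expected.n_dloop_lots} D-loop lots")


if __name__ == "__main__":
    main()
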