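"""Treatment-effect statistics on the simulated lineage.

Runs the Shapiro-gated location battery: diploid 28S copy number across
the four treatment groups (outlier-aware), and square-root-transformed
absolute change rates across treatments — mirroring how metal effects
are assessed on the real lines. Under the simulator's null (the event
rate does not depend on treatment) neither test should be significant.
Writes results/stats_report.tsv.
"""

from pathlib import Path

import pandas as pd

from rdnavar.copy_number import flag_outliers_iqr
from rdnavar.io_formats import (metadata_frame, read_metadata, read_table,
                                write_table)
from rdnavar.stats import gated_location_test

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cn = read_table(ROOT / "results" / "copy_number.tsv")
    meta = metadata_frame(read_metadata(
        ROOT / "results" / "sim" / "sx" / "metadata.tsv"))
    table = cn[cn["region"] == "28S"].merge(meta, on="sample_id")
    rates = read_table(ROOT / "results" / "change_rates.tsv").rename(
        columns={"line_id": "sample_id"}).merge(meta, on="sample_id")

    rows = []
    groups = {t: g["diploid_cn"].to_numpy() for t, g in table.groupby("treatment")}
    ids = {t: list(g["sample_id"]) for t, g in table.groupby("treatment")}
    outliers = table.loc[flag_outliers_iqr(table["diploid_cn"].to_numpy()),
                         "sample_id"].tolist()
    exclude = {t: [s for s in outliers if s in ids[t]] for t in ids}
    for label, excl in [("cn_by_treatment", None),
                        ("cn_by_treatment_no_outliers", exclude)]:
        res = gated_location_test(groups, exclude=excl, sample_ids=ids)
        rows.append({"test": label, "branch": res.branch,
                     "shapiro_p": res.shapiro_p, "statistic": res.statistic,
                     "p": res.p, "excluded": ";".join(res.excluded_samples)})
        print(f"{label}: {res.branch}, Shapiro P = {res.shapiro_p:.3f}, "
              f"stat = {res.statistic:.2f}, P = {res.p:.3f}"
              + (f" (excluded {res.excluded_samples})" if res.excluded_samples
                 else ""))

    rate_groups = {t: g["abs_rate"].to_numpy() for t, g in rates.groupby("treatment")}
    res = gated_location_test(rate_groups, transform="sqrt")
    rows.append({"test": "abs_rate_by_treatment_sqrt", "branch": res.branch,
                 "shapiro_p": res.shapiro_p, "statistic": res.statistic,
                 "p": res.p, "excluded": ""})
    print(f"abs rate (sqrt) by treatment: {res.branch}, "
          f"Shapiro P = {res.shapiro_p:.3f}, stat = {res.statistic:.2f}, "
          f"P = {res.p:.3f}")
    write_table(pd.DataFrame(rows), ROOT / "results" / "stats_report.tsv")


if __name__ == "__main__":
    main()
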