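"""Length-variability statistics: the OIE-vs-nonOIE dispersion comparison.

For each curated set, computes per-lifestyle outlier-excluded range, sample
SD and IQR of total lengths, classifies each set, and compares per-set
dispersion between lifestyles (Welch t-test, Mann–Whitney). Writes
dispersion.tsv, classification.tsv, group_comparison.tsv, regressions.tsv,
bubbles.tsv and variance_of_averages.tsv under results/.

Note on the regression table: the generator draws ortholog length
independently of genome size (the lifestyle contrast is variance-only), so
average ortholog length vs genome size is expected — and reported — to show
a near-zero slope here.
"""

from _common import RESULTS_DIR, ensure_data

from endoshrink import pipeline


def main() -> None:
    inputs = pipeline.load_bundle_dir(ensure_data())
    RESULTS_DIR.mkdir(exist_ok=True)
    sets, _ = pipeline.run_curation(inputs)
    decomps = pipeline.run_decomposition(sets)
    res = pipeline.run_variability(sets, decomps, inputs.meta, RESULTS_DIR)

    n = len(sets)
    print(f"classification over {n} curated sets (total length):")
    for metric in ("range", "sd", "iqr"):
        rows = [r for r in res["summary"] if r["metric"] == metric]
        parts = ", ".join(
            f"{r['category']} {r['count']} ({r['percent']:.1f}%)" for r in rows
            if r["count"]
        )
        print(f"  {metric:>5}: {parts}")
    print("per-set dispersion, OIE vs nonOIE:")
    for row in res["comparison"]:
        print(
            f"  {row['metric']:>5}: nonOIE avg {row['nonOIE_average']:.2f}, "
            f"OIE avg {row['OIE_average']:.2f}, t-test p {row['t_test_p']:.3g}, "
            f"Mann-Whitney p {row['mann_whitney_p']:.3g}"
        )
    var = res["variance_of_averages"]
    print(f"variance of species-average lengths: OIE {var['OIE']:.2f}, "
          f"nonOIE {var['nonOIE']:.2f}")
    if res["regression"]:
        fit = res["regression"]
        print(f"avg length ~ genome size: slope {fit.slope:.3f}, "
              f"R^2 {fit.r_squared:.3f}, p {fit.p_value:.3g} (n={fit.n})")


if __name__ == "__main__":
    main()
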