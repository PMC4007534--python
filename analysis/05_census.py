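"""Maximum-protein-length census: are large proteins missing from OIE proteomes?

Derives the clade cutoff (longest OIE protein), lists every nonOIE protein
strictly longer, categorizes them core vs secondary/unknown from the bundle's
category map, compares category lengths (Mann–Whitney), and checks each large
protein for a shortened OIE ortholog (>65% identity over >80% of the OIE
protein). Writes max_lengths.tsv, census.tsv and category_comparison.tsv
under results/.
"""

from _common import RESULTS_DIR, ensure_data

from endoshrink import pipeline


def main() -> None:
    inputs = pipeline.load_bundle_dir(ensure_data())
    RESULTS_DIR.mkdir(exist_ok=True)
    res = pipeline.run_census(inputs, out_dir=RESULTS_DIR)
    entries = res["entries"]
    print(f"census cutoff (longest OIE protein): {res['cutoff'].cutoff_aa} aa")
    print(f"large nonOIE proteins: {len(entries)}")
    for cat in ("core", "secondary_or_unknown", "unassigned"):
        of_cat = [e for e in entries if e.category == cat]
        if of_cat:
            with_orth = sum(e.oie_ortholog_found for e in of_cat)
            print(f"  {cat}: {len(of_cat)} "
                  f"(OIE ortholog found for {with_orth})")
    if res["comparison"]:
        c = res["comparison"]
        print(f"core vs secondary lengths: chi2 {c['chi2']:.1f}, p {c['p']:.3g} "
              f"(core median {c['core_median']:.0f} aa, "
              f"secondary median {c['secondary_median']:.0f} aa)")
    print(f"tables: {RESULTS_DIR}/max_lengths.tsv, census.tsv, "
          f"category_comparison.tsv")


if __name__ == "__main__":
    main()
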