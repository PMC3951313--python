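"""Reproduce the headline census-summary arithmetic from the published
per-colony means: the western Ross Sea grand total, the southern
metapopulation's share, Cape Crozier's share of the southern sum, and how
2012 counts compare with the 30-year means.
"""

from rookery import make_fixture, regional_totals

df = make_fixture("published_means")
southern = ["Cape Royds", "Cape Bird", "Cape Crozier", "Beaufort Island"]

out = regional_totals(
    df, southern, largest_id="Cape Crozier",
    ratio_ids=["Cape Bird", "Cape Crozier"],
)

print(f"grand total of mean counts: {out['grand_total']:,.0f} breeding pairs")
print(f"southern metapopulation share: {out['southern_share_pct']}%")
print(f"Cape Crozier share of the southern sum: "
      f"{out['largest_share_of_southern_pct']}%")
print(f"Bird+Crozier 2012 counts vs their means: "
      f"{out['latest_to_mean_ratio']}x")
print("\nThe two largest colonies held nearly twice their 30-year average "
      "in 2012 — the recent growth era dominates the southern record.")
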