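"""Prorate individual and group 4-item SWLS scores onto the 5-item metric.

Proration adds the mean of the four retained items to their sum, so a
4-item sum maps to 1.25 x sum4.  The crosswalk table enumerates the
mapping for every possible 4-item sum.
"""

from swlslink import classify, crosswalk_table, group_prorated_mean, prorated_score

for responses in ([7, 7, 7, 7], [1, 1, 1, 1], [3, 4, 5, 6]):
    p = prorated_score(responses)
    print(f"responses {responses} -> prorated {p:5.2f} ({classify(p).label})")

# group level: the published overall item means for items 1-4
item_means = (3.76, 3.80, 4.32, 4.53)
group = group_prorated_mean(sum(item_means))
print(f"\ngroup item means {item_means} -> prorated group mean {group:.4f} "
      f"(displayed {group:.1f})")
# 20.5 is the 5-item-metric estimate of the group's mean satisfaction.

print("\ncrosswalk (first and last rows):")
tab = crosswalk_table()
print(tab.head(3).to_string(index=False))
print(tab.tail(3).to_string(index=False))
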