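# Simplified Lung-RADS v2022 baseline volume criteria (categories 2/3/4A/4B).
# Volume cutpoints in mm^3, transcribed from the ACR Lung-RADS v2022 volume
# thresholds (solid 113/268/1767 mm^3 ~ 6/8/15 mm diameter equivalents;
# part-solid: total >= 113 mm^3 gate, then solid component 113/268 mm^3;
# non-solid 3351 mm^3 ~ 30 mm).  Intervals are closed-open: a volume equal
# to a cutpoint falls in the higher category.
version: v2022-simplified
categories: ["2", "3", "4A", "4B"]
solid:
  # categorized on total volume (== solid volume for a solid nodule)
  total_cutpoints_mm3: [113.0, 268.0, 1767.0]
  total_categories: ["2", "3", "4A", "4B"]
part_solid:
  # total volume below the gate -> category 2; otherwise categorized on the
  # solid component
  total_floor_mm3: 113.0
  floor_category: "2"
  solid_cutpoints_mm3: [113.0, 268.0]
  solid_categories: ["3", "4A", "4B"]
ggn:
  # non-solid nodules categorized on total volume only
  total_cutpoints_mm3: [3351.0]
  total_categories: ["2", "3"]
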