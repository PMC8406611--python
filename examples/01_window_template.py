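"""Tile a small two-gene panel with sliding windows and inspect the geometry.

Windows are 75 nt sliding by 10 nt, so adjacent windows overlap by 65 nt and
the last window of each region stretches to absorb the remainder — windows
never cross a region boundary.
"""

from panelcnv import TargetRegion, WindowTemplate, count_windows

regions = [
    TargetRegion("chr2", 47_403_067, 47_403_201, gene="MSH2_like", label="exon1"),
    TargetRegion("chr2", 47_408_400, 47_408_475, gene="MSH2_like", label="exon2"),
    TargetRegion("chr2", 47_412_244, 47_412_284, gene="MSH2_like", label="exon3"),
]
template = WindowTemplate(regions, window_len=75, slide_len=10)

for r in regions:
    n = count_windows(r.length, 75, 10)
    print(f"{r.label}: {r.length} nt -> {n} window(s)")

print(f"\ntotal: {template.n_windows} windows over {template.n_positions} targeted nt")

wins = [w for w in template.windows if w.region_label == "exon1"]
print("\nexon1 window layout (0-based half-open):")
for w in wins:
    print(f"  {w.start}-{w.end}  ({w.length} nt)")
overlap = wins[0].end - wins[1].start
print(f"adjacent windows overlap by {overlap} nt; "
      f"the last window is {wins[-1].length} nt because it absorbs the remainder")
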