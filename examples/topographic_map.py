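"""Topographic map: entropy-driven competition orders receptive fields.

A 10 x 10 input sheet feeds a 10 x 10 output sheet with purely excitatory
lateral interaction K = exp(-r^2). The learning rule dW ~ K W Q +
T (I - W W') W (with row normalization) adds an entropy-maximizing
competition term that prevents output neurons from copying each other;
at T = 0.1 the receptive-field centers spread into an ordered grid.
"""

from thermoneuro.feature_map import develop_topographic_map, map_metrics

for T in (0.1, 0.0):
    res = develop_topographic_map(grid_n=10, T=T, steps=2000, seed=1)
    order = map_metrics(res)["topographic_order"]
    spread = res.rf_centers.std(axis=0)
    print(f"T = {T}: topographic order {order:+.3f}, "
          f"RF-center spread ({spread[0]:.2f}, {spread[1]:.2f})")
print()
print("Order is the Spearman correlation between pairwise distances on the")
print("output grid and between receptive-field centers: ~0.96 is a globally")
print("ordered map, while the T = 0 control collapses every center onto one")
print("point (spread ~0, order ~0).")
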