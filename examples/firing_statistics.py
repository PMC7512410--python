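"""Spike-timing firing statistics: exact trace, cluster expansion, Monte Carlo.

A presynaptic neuron fires once at t = 0 into an excitatory synapse; the
postsynaptic firing probability per bin rho(t) is computed three ways:
exact enumeration of all spatiotemporal configurations, the truncated
fugacity/Mayer expansion, and a conditional-rate Monte Carlo.
"""

from thermoneuro.cli import fey_rate_table

rows = fey_rate_table(w=0.8, bias=-4.0, T=1.0, n_bins=8, dt=1.0,
                      n_trials=5000, order=3, seed=1)
print(f"{'t':>3} {'exact':>10} {'expansion':>10} {'monte carlo':>12}")
for t, exact, approx, mc in rows:
    print(f"{t:3.0f} {exact:10.5f} {approx:10.5f} {mc:12.5f}")
print()
print("The synaptic kernel raises the firing probability above the baseline")
print("exp(B/T)/(1+exp(B/T)) in the bins after the presynaptic spike; the")
print("third-order expansion tracks the exact trace to a few parts in 1e4")
print("at this coupling, and the Monte Carlo agrees within sampling error.")
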