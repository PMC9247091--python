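"""FITC-dextran standard curve and comparative-Ct (ddCt) qPCR helpers."""

import pandas as pd

import dexil

# standard curve: fluorescence readings -> tracer concentration (ug/ml)
curve = dexil.fit_standard_curve(
    fluorescence=[0, 50, 100, 200, 400], concentration=[0, 5, 10, 20, 40]
)
print(f"curve: conc = {curve.slope:.3f} * F + {curve.intercept:.3f}, R^2 = {curve.r_squared:.4f}")
out = dexil.fluorescence_to_concentration(curve, [250, 600])
print(out.round(2).to_string(index=False))
# 600 sits above the calibrated range and is flagged as extrapolated.

# ddCt: target normalized to the mean of two reference genes, then to control
cts = pd.DataFrame(
    [
        ("ctrl", "MUC5B", 26.0), ("ctrl", "RPL13A", 20.0), ("ctrl", "SDHA", 22.0),
        ("il17", "MUC5B", 24.0), ("il17", "RPL13A", 20.0), ("il17", "SDHA", 22.0),
    ],
    columns=["sample_id", "gene", "ct"],
)
rq = dexil.ddct_relative_expression(cts, "MUC5B", ["RPL13A", "SDHA"], ["ctrl"])
print(rq.round(3).to_string(index=False))
# MUC5B amplifies two cycles earlier under IL-17A: 4-fold induction (RQ = 4).
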