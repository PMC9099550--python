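"""Transport metrics of a carrier vs a pneumatic-tube trace.

Generates one synthetic trace per transport mode and prints the vibration
metrics. Expect the pneumatic tube to sit roughly an order of magnitude
above the carrier on TK/RMS/VDV, with ~100+ shocks above 2.5 g, while the
carrier shows a ~4 Hz gait line and no shocks.
"""

from cevtransport import accelerometry as acc
from cevtransport import synth

for mode in ("C", "PTS"):
    trace = synth.gen_accel_trace(mode, seed=1)
    m = acc.summarize_transport(trace, with_ground_frequency=(mode == "C"))
    print(f"--- {mode} ({m.duration:.1f} min) ---")
    print(f"  TK   {m.tk:8.4f} g^2   (mean Teager-Kaiser energy)")
    print(f"  RMS  {m.rms:8.4f} g     (mean acceleration)")
    print(f"  VDV  {m.vdv:8.4f} g*s^0.25 (shock-weighted vibration dose)")
    print(f"  shocks > 2.5 g: {m.shock_count}")
    print(f"  max / median amplitude: {m.max_amplitude:.2f} / {m.median_amplitude:.2f} g")
    if m.ground_frequency is not None:
        print(f"  ground frequency: {m.ground_frequency:.2f} Hz (walker gait)")
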