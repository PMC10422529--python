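"""Down-sample a pressure frame across the full configuration grid.

Block pooling averages k x k sensor regions (emulating a coarser, cheaper
array); decimation keeps one frame every n seconds (a slower sampler).
The 25 combinations below are the grid the sensitivity analysis sweeps.
"""

from ipmap import (
    BodyModel,
    ImmersionModel,
    block_pool,
    enumerate_configurations,
    render_static_frame,
)

frame = render_static_frame(BodyModel.default(), "supine", ImmersionModel.foam())
print(f"native array: {frame.shape[0]} x {frame.shape[1]} = "
      f"{frame.shape[0] * frame.shape[1]} sensors\n")

print("pooled arrays:")
for k in (2, 3, 4, 5):
    pooled = block_pool(frame, k)
    rows, cols = pooled.shape
    print(f"  k={k}: {rows} x {cols} = {rows * cols:5d} sensors, "
          f"pitch {pooled.pitch:.1f} mm")

print("\nconfiguration grid (n_sensors x sampling frequency):")
configs = enumerate_configurations(118, 48)
frequencies = sorted({c.frequency_label for c in configs},
                     key=lambda s: -float(s))
header = "  n_sensors " + "".join(f"{f + ' Hz':>9s}" for f in frequencies)
print(header)
for k in (1, 2, 3, 4, 5):
    row = [c for c in configs if c.block == k]
    print(f"  {row[0].n_sensors:9d} " + "".join(" " * 6 + "x  " for _ in row))

# Each 'x' is one analysis cell: the pipeline scores event discrimination
# (AUC) in every cell and posture classification at every spatial
# resolution.
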