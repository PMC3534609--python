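"""Build net energy intake from primary measurements (week S24).

Reconstructs the last starvation week's energy bookkeeping: resting
expenditure from indirect calorimetry (139.1 cc O₂/min at 4.964 kcal/L),
the walking programme costs scaled to the group's 52.57 kg weight, their
sum (TEE), and the net intake that forces the weight recursion.
"""

from weightdiffusion import (
    ActivityProfile,
    RestingMeasurement,
    load_group_series,
    net_energy_intake,
    resting_ee,
    total_ee,
    treadmill_ee,
    walking_ee,
)

ree = resting_ee(RestingMeasurement(oxygen_consumption=139.1, caloric_equivalent=4.964))
profile = ActivityProfile(body_weight=52.57)
walk = walking_ee(profile)
tread = treadmill_ee(profile)
tee = total_ee(ree, [walk, tread])

intake = load_group_series().record_at("S24").mean_intake
net = net_energy_intake(intake, tee)

print(f"REE (resting)          = {ree:8.2f} kcal/day")
print(f"AEE outdoor walking    = {walk:8.2f} kcal/day  (22 mi/wk at 3 mph)")
print(f"AEE treadmill          = {tread:8.2f} kcal/day  (30 min/wk at 3.5 mph)")
print(f"TEE (total)            = {tee:8.2f} kcal/day")
print(f"food intake            = {intake:8.2f} kcal/day")
print(f"net energy intake      = {net:8.2f} kcal/day")
print("\nA positive net intake in late starvation reflects the falling TEE:")
print("expenditure adapts downward faster than the restricted diet.")
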