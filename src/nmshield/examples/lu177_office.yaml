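# Packaged example: a Lu-177 DOTATATE treatment room separated from an
# adjacent office by a wall.  Five 200 mCi administrations per week, each
# patient present for 4 hours (decay ignored); the point of concern sits
# 30 cm behind an 11.4 cm wall whose inner face is 1.98 m from the patient,
# and is shielded to the US public limit of 20 uGy per week.
nuclide: Lu-177
workload:
  activity_mCi: 200
  hours: 4
  sessions_per_week: 5
  apply_decay: false
source_to_barrier_cm: 198.6
wall_thickness_cm: 11.4
barrier_to_poc_cm: 30
limit_uGy_per_week: 20
occupancy: 1.0
material: lead
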