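# Default 'bci-like' synthetic scenario: 30-camera grid, 90-day sessions,
# one rare mostly-nocturnal predator ~100x rarer than the prey pool,
# five mostly-diurnal prey with steep rank abundance, occasional camera
# failures, and planted avoidance/tracking interaction effects.
n_locations: 30
session_days: 90.0
n_sessions: 3
failure_prob: 0.1
seed: 0
species:
- name: ocelot
  role: predator
  base_rate: 0.03
  diel:
  - - 2.0
    - 1.5
    - 0.7
  - - 14.0
    - 0.3
    - 0.3
- name: agouti
  role: prey
  base_rate: 2.0
  diel:
  - - 8.0
    - 2.0
    - 0.5
  - - 16.0
    - 2.0
    - 0.5
- name: peccary
  role: prey
  base_rate: 0.5
  diel:
  - - 11.0
    - 1.0
    - 1.0
- name: paca
  role: prey
  base_rate: 0.25
  diel:
  - - 22.0
    - 2.0
    - 1.0
- name: coati
  role: prey
  base_rate: 0.1
  diel:
  - - 12.0
    - 1.5
    - 1.0
- name: tinamou
  role: prey
  base_rate: 0.05
  diel:
  - - 9.0
    - 1.0
    - 1.0
- name: human
  role: nontarget
  base_rate: 0.005
  diel:
  - - 11.0
    - 2.0
    - 1.0
interactions:
- trigger_role: predator
  responder_role: prey
  theta: 0.5
  window_h: 12.0
  decay: step
- trigger_role: prey
  responder_role: predator
  theta: 4.0
  window_h: 6.0
  decay: step
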