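# Synthetic binding-pocket generator defaults.
#
# Schema: cluster_weights -- early-Lumi-R mixture weights (Cl0, Cl1, Cl2);
# tau_late_us -- mean of the exponential early->late switching time (us);
# frame_interval_us / replica_length_us / n_replicas -- relaxation-replica
# sampling; emissions -- per-state feature distributions in angstrom:
# {kind: gauss, mean, sd} or {kind: mix2, mean1, sd1, mean2, sd2, w1};
# indicator features (water_bridge_OD, pyrrole_water_D) are probabilities.
#
# All values are generator conventions reproducing the qualitative contrasts
# of the modelled pocket (shorter/longer distances, unimodal vs bimodal,
# cluster weights); none are measured quantities.
cluster_weights:
- 0.18
- 0.81
- 0.01
tau_late_us: 0.4
frame_interval_us: 0.0001
replica_length_us: 2.0
n_replicas: 10
emissions:
  pr:
    OD_His290:
      kind: gauss
      mean: 3.1
      sd: 0.4
    OD_water:
      kind: gauss
      mean: 2.9
      sd: 0.3
    Tyr263_Asp207:
      kind: gauss
      mean: 2.7
      sd: 0.2
    ND_Tyr263:
      kind: gauss
      mean: 5.6
      sd: 0.7
    OD_Arg466:
      kind: gauss
      mean: 5.0
      sd: 0.45
    OB_Ser257:
      kind: gauss
      mean: 2.8
      sd: 0.25
    OB_Tyr216:
      kind: gauss
      mean: 4.5
      sd: 0.55
    Asp207_Arg466_c1:
      kind: gauss
      mean: 2.75
      sd: 0.28
    Asp207_Arg466_c2:
      kind: gauss
      mean: 2.85
      sd: 0.3
    water_bridge_OD: 0.7
    pyrrole_water_D: 0.1
  early:
    OD_His290:
      kind: gauss
      mean: 4.6
      sd: 0.7
    OD_water:
      kind: gauss
      mean: 2.85
      sd: 0.22
    Tyr263_Asp207:
      kind: gauss
      mean: 2.75
      sd: 0.22
    ND_Tyr263:
      kind: gauss
      mean: 3.0
      sd: 0.25
    OD_Arg466:
      kind: gauss
      mean: 5.2
      sd: 0.35
    OB_Ser257:
      kind: gauss
      mean: 2.8
      sd: 0.25
    OB_Tyr216:
      kind: gauss
      mean: 4.2
      sd: 0.5
    Asp207_Arg466_c1:
      kind: gauss
      mean: 2.7
      sd: 0.25
    Asp207_Arg466_c2:
      kind: gauss
      mean: 2.8
      sd: 0.28
    water_bridge_OD: 0.92
    pyrrole_water_D: 0.15
  early_cluster_overrides:
    0: {}
    1:
      OD_water:
        kind: gauss
        mean: 5.2
        sd: 0.5
      water_bridge_OD: 0.05
      OD_His290:
        kind: gauss
        mean: 5.8
        sd: 0.7
      OB_Ser257:
        kind: gauss
        mean: 3.25
        sd: 0.28
      OB_Tyr216:
        kind: gauss
        mean: 5.1
        sd: 0.5
    2:
      Tyr263_Asp207:
        kind: gauss
        mean: 5.6
        sd: 0.55
      ND_Tyr263:
        kind: gauss
        mean: 3.6
        sd: 0.35
  late:
    OD_His290:
      kind: gauss
      mean: 5.0
      sd: 0.9
    OD_water:
      kind: gauss
      mean: 3.6
      sd: 0.8
    Tyr263_Asp207:
      kind: gauss
      mean: 5.0
      sd: 0.95
    ND_Tyr263:
      kind: gauss
      mean: 4.8
      sd: 0.85
    OD_Arg466:
      kind: mix2
      mean1: 3.2
      sd1: 0.35
      mean2: 5.8
      sd2: 0.55
      w1: 0.45
    OB_Ser257:
      kind: gauss
      mean: 4.2
      sd: 0.75
    OB_Tyr216:
      kind: gauss
      mean: 2.9
      sd: 0.3
    Asp207_Arg466_c1:
      kind: gauss
      mean: 3.3
      sd: 0.6
    Asp207_Arg466_c2:
      kind: gauss
      mean: 3.6
      sd: 0.65
    water_bridge_OD: 0.3
    pyrrole_water_D: 0.75
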