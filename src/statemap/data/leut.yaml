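# LeuT default analysis definitions.
#
# Segments: the five Calpha helix segments whose pairwise CoM distances
# discriminate the transport-cycle states (TM1b-TM10ec and TM6a-TM10ec
# report on the EC vestibule, TM1a-TM6b on the IC vestibule).
#
# Gates: IC gating pairs R5-D369 (salt bridge) and W8-Y268/Y265
# (H-bond triple), EC gates R30-D404 (salt bridge) and F253-Y108
# (aromatic contact), plus the N-terminal salt bridge E6-R375.
# Closed-state cutoffs are field-standard defaults, configurable here.
#
# Templates: per-state means/SDs (Å) of the three interhelical distances
# in the order [TM1b-TM10ec, TM6a-TM10ec, TM1a-TM6b], the required gate
# logic and the substrate-bound flag.  Starred states are substrate
# bound; OFo*/IFo* share helix-packing templates with OFo/IFo.

segments:
  TM1a:   {first: 11,  last: 22}
  TM1b:   {first: 25,  last: 35}
  TM6a:   {first: 242, last: 255}
  TM6b:   {first: 259, last: 268}
  TM10ec: {first: 398, last: 412}

descriptor_pairs:
  - [TM1b, TM10ec]
  - [TM6a, TM10ec]
  - [TM1a, TM6b]

gates:
  r5_d369:
    kind: salt_bridge
    a: {first: 5, last: 5, atoms: [NH1, NH2, NE]}
    b: {first: 369, last: 369, atoms: [OD1, OD2]}
    cutoff: 4.0
  e6_r375:
    kind: salt_bridge
    a: {first: 6, last: 6, atoms: [OE1, OE2]}
    b: {first: 375, last: 375, atoms: [NH1, NH2, NE]}
    cutoff: 4.0
  r30_d404:
    kind: salt_bridge
    a: {first: 30, last: 30, atoms: [NH1, NH2, NE]}
    b: {first: 404, last: 404, atoms: [OD1, OD2]}
    cutoff: 4.0
  w8_y268:
    kind: hbond
    a: {first: 8, last: 8, atoms: [NE1]}
    b: {first: 265, last: 268, atoms: [OH]}
    cutoff: 3.5
  f253_y108:
    kind: contact
    a: {first: 253, last: 253, atoms: [CZ]}
    b: {first: 108, last: 108, atoms: [OH, CZ]}
    cutoff: 5.0

ec_gates: [r30_d404, f253_y108]

regions:
  EC_vestibule:  {anchors: [TM1b, TM10ec], radius: 8.0}
  IC_vestibule:  {anchors: [TM1a, TM6b],  radius: 8.0}
  binding_pocket: {anchors: [TM1a, TM1b, TM6a, TM6b, TM10ec], radius: 6.0}

templates:
  OFo:
    means: [18.0, 16.8, 11.6]
    sds:   [0.6, 0.4, 0.2]
    substrate_bound: false
    ec_rule: both_open
    gates: {r5_d369: closed, e6_r375: closed}
    tilt: 5.0
  OFo_star:
    means: [18.0, 16.8, 11.6]
    sds:   [0.6, 0.4, 0.2]
    substrate_bound: true
    ec_rule: both_open
    gates: {r5_d369: closed, e6_r375: closed}
    tilt: 5.0
  OFc_star:
    means: [16.8, 13.8, 11.7]
    sds:   [0.3, 0.3, 0.2]
    substrate_bound: true
    ec_rule: at_least_one_closed
    gates: {r5_d369: closed, e6_r375: closed}
    tilt: 5.0
  holo_occluded:
    means: [15.8, 12.5, 12.8]
    sds:   [0.4, 0.4, 0.4]
    substrate_bound: true
    ec_rule: at_least_one_closed
    gates: {r5_d369: open, e6_r375: open, w8_y268: closed}
    tilt: 10.0
  IFo_star:
    means: [14.3, 12.2, 20.5]
    sds:   [0.4, 0.4, 2.0]
    substrate_bound: true
    ec_rule: at_least_one_closed
    gates: {r5_d369: open, w8_y268: open}
    tilt: 45.0
  IFo:
    means: [14.3, 12.2, 20.5]
    sds:   [0.4, 0.4, 2.0]
    substrate_bound: false
    ec_rule: at_least_one_closed
    gates: {r5_d369: open}
    tilt: 45.0
  apo_occluded:
    means: [14.5, 13.2, 12.2]
    sds:   [0.4, 0.3, 0.3]
    substrate_bound: false
    ec_rule: at_least_one_closed
    gates: {r5_d369: closed, e6_r375: closed}
    tilt: 10.0

cycle_order: [OFo, OFc_star, holo_occluded, IFo_star, IFo, apo_occluded]

crystal_reference:
  # deposited-structure descriptor values (Å) for the two resolved
  # end states, order [TM1b-TM10ec, TM6a-TM10ec, TM1a-TM6b]
  OFc_star: {pdb_id: 2A65, distances: [16.2, 13.8, 11.6]}
  IFo:      {pdb_id: 3TT3, distances: [13.8, 11.5, 22.6]}
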