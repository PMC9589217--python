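# Stiffness parameters of the tibiofemoral ligament bundles.
#
# k1 is the quadratic (toe-region) coefficient in N/mm^2, k2 the linear
# coefficient in N/mm.  Each ligament is discretised into the listed
# number of parallel bundles; bundles of the same ligament share the
# stiffness constants.  The reference-strain constant eps_l applies to
# every bundle.
eps_l: 0.03
ligaments:
  ACL:
    - {bundle: anterior,  n: 2, k1: 22.48, k2: 83.15}
    - {bundle: posterior, n: 2, k1: 26.27, k2: 83.15}
  PCL:
    - {bundle: anterior,  n: 2, k1: 31.26, k2: 125.00}
    - {bundle: posterior, n: 2, k1: 19.29, k2: 60.00}
  MCL:
    - {bundle: anterior,  n: 1, k1: 10.00, k2: 91.25}
    - {bundle: oblique,   n: 1, k1: 5.00,  k2: 27.86}
    - {bundle: deep,      n: 1, k1: 5.00,  k2: 21.07}
  PMC:
    - {bundle: main, n: 3, k1: 12.00, k2: 52.59}
  LCL:
    - {bundle: main, n: 3, k1: 10.00, k2: 72.22}
  ALS:
    - {bundle: main, n: 3, k1: 5.00,  k2: 19.00}
  OPL:
    - {bundle: main, n: 3, k1: 3.00,  k2: 21.42}
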