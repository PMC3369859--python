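# Diagnostic-marker hierarchy for bovine mtDNA haplogroup T1.
#
# Marker labels use the field notation relative to the Bovine Reference
# Sequence: bare numbers are transitions, "+X" insertions, "d" deletions and a
# leading "@" declares that the clade LACKS the mutation (a reversion toward
# the reference state is part of its definition).
#
# Users may extend this file with further clades (other T haplogroups, P/Q/R)
# without code changes; only the T1 portion ships validated.
name: bovine-T1
version: 1
root: T1
unstable_positions: [16050, 16113, 16122]
nodes:
  - name: T1
    parent: null
    markers: ["16050", "16113", "16255"]
  - name: T1a
    parent: T1
    markers: ["2055+C"]
  - name: T1b
    parent: T1
    markers: ["7542"]
  - name: T1b1
    parent: T1b
    markers: ["16022"]
  - name: T1c
    parent: T1
    markers: ["16122"]
  - name: T1c1
    parent: T1c
    markers: ["16196"]
  - name: T1c1a
    parent: T1c1
    markers: ["16053"]
  - name: T1c1a1
    parent: T1c1a
    markers: ["1324", "11542", "16139"]
  - name: T1d
    parent: T1
    markers: ["6235"]
  - name: T1d1
    parent: T1d
    markers: ["4856", "1600d"]
  - name: T1e
    parent: T1
    markers: ["8", "@16050"]
  - name: T1f
    parent: T1
    markers: ["12492", "@16113"]
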