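# Deposited structures

The structural reproductions (interface areas, interface-residue
fractions, cross-structure RMSD, symmetry-mate interfaces) run on two
deposited Protein Data Bank entries that are not distributed with this
package:

- `4yo2.pdb` — the tandem-DBD E2F8/DNA complex (hexagonal form)
- `1cf7.pdb` — the E2F4/DP2/DNA heterodimer complex

Download them into this directory, e.g.:

```sh
curl -o 4yo2.pdb https://files.rcsb.org/download/4YO2.pdb
curl -o 1cf7.pdb https://files.rcsb.org/download/1CF7.pdb
```

Until the files are present, the four deposited-structure tests in
`tests/test_acceptance.py` fail with a pointer to this note, and
`scripts/acceptance.py` reports the synthetic-data quantities only.
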