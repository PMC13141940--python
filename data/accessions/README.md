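# Deposited inputs (user-supplied)

The reproduction tests in `tests/test_acceptance.py` and the worked examples
that analyze the real crystal and solution data consume the public deposits
for the TurB N-terminal domain study. They are not redistributed with this
repository; download them and place them here:

| file (any of the listed names)       | source                                   |
|--------------------------------------|------------------------------------------|
| `8h8h.cif` / `8h8h.pdb` (optionally `.gz`) | wwPDB entry **8H8H** (TurB_nt_50, 8 chains) |
| `5b52.cif` / `5b52.pdb` (optionally `.gz`) | wwPDB entry **5B52** (TurB_nt_61-R8A)        |
| `sasdup4.dat`                        | SASBDB entry **SASDUP4**, the subtracted/averaged solution scattering profile (3-column `q I sigma` text) |

For example:

    curl -O https://files.rcsb.org/download/8H8H.cif
    curl -O https://files.rcsb.org/download/5B52.cif

then rename to lower case. Without these files the reproduction tests fail
with a message pointing here; the synthetic-data test suite is unaffected.
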