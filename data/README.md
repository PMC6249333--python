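# data/

Place the deposited per-specimen measurement files of the *Pteromalus*
delimitation study here to enable the checks that use them:

- `oo_153288.csv` — measurements for *P. capito*, *P. albipennis* and
  *P. cingulipes* (drives the variance-explained and best-ratio checks);
- `oo_153287.csv` — the *P. capito* type-series measurements and ratios
  (drives the printed-range check).

The files are distributed with the study's supplementary material and
on its public data deposit; they are not redistributed in this
repository.  Without them the corresponding tests in
`tests/test_acceptance.py` fail with an explicit message; every other
test is self-contained.
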