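"""Molecular shape classification from the critical packing parameter.

s = V / (a * l_c) maps chain volume V (A^3), head-group area a (A^2)
and critical chain length l_c (A) onto a mean molecular shape, used to
rationalize packing complementarity in mixed films. The geometry values
below are illustrative, not measured.
"""

from monothermo import Component, assess_shape

illustrative = [
    Component("POPC", role="phospholipid", geometry=(400.0, 70.0, 17.5)),
    Component("SM", role="sphingolipid", geometry=(1050.0, 58.0, 20.0)),
    Component("CHOL", role="sterol", geometry=(630.0, 19.0, 10.0)),
    Component("7KC", role="sterol", geometry=(640.0, 26.0, 10.0)),
]

print(f"{'component':10s} {'s':>6s}  shape")
for comp in illustrative:
    result = assess_shape(comp)
    print(f"{comp.component_id:10s} {result.s:6.2f}  {result.shape}")

# A small head group (cholesterol) pushes s above 3 (inverted cone);
# the bulkier oxidized polar part of 7-ketocholesterol lowers s into
# the inverted-truncated-cone band, degrading its packing
# complementarity with conical phosphatidylcholines.
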