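name = "simple-example"
compounds = ["x1", "x2", "x3", "x4"]
important = ["x1", "x4"]

[[complexes]]
name = "x1"
stoichiometry = { x1 = 1 }

[[complexes]]
name = "x2"
stoichiometry = { x2 = 1 }

[[complexes]]
name = "x3"
stoichiometry = { x3 = 1 }

[[complexes]]
name = "x4"
stoichiometry = { x4 = 1 }

[[reactions]]
name = "k1"
substrate = "x1"
product = "x2"
modifier = "mass_action"

[[reactions]]
name = "k2"
substrate = "x1"
product = "x3"
modifier = "mass_action"

[[reactions]]
name = "k3"
substrate = "x2"
product = "x4"
modifier = "mass_action"

[[reactions]]
name = "k4"
substrate = "x3"
product = "x4"
modifier = "mass_action"

[[boundary]]
name = "k5"
complex = "x1"
kind = "inflow"

[[boundary]]
name = "k6"
complex = "x4"
kind = "outflow"

[kinetic_parameters]
k1 = 0.44
k2 = 0.03
k3 = 0.55
k4 = 0.44

[boundary_parameters]
k5 = 0.42
k6 = 0.33

[initial_values]
x1 = 0.4
x2 = 0.0
x3 = 0.5
x4 = 0.4
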