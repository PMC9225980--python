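# Default algae (A) - zooplankton (Z) parameterization of the
# consumer-resource models (Scheffer-style lake plankton values).
# Units: densities in resource/consumer units, rates per time unit.

[params]
r = 0.5    # max resource growth rate
K = 10.0   # carrying capacity (upper end of the eutrophication gradient)
g = 0.4    # max consumer intake rate
a = 0.6    # half-saturation of consumer on resource
l = 0.01   # resource loss rate (and chemostat influx coefficient)
e = 0.6    # conversion efficiency
m = 0.15   # consumer loss rate
F = 0.0    # max top-consumer intake (gradient parameter, 0 when absent)
z = 0.5    # half-saturation of top-consumer on consumer

[gradients]
K = [0.0, 10.0]
F = [0.0, 0.3]
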