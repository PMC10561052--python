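# Synthetic calibrated reference parameter set (linear space, molecules & seconds).
#
# This is NOT a published fit: it is a stand-in calibrated so that the model
# reproduces the reported reference behaviour -- full IKK complex activation
# near 13 Gy, signalosome-flux AUC of ~98,000 molecules at 15 Gy dropping to
# ~59,000 under 90% inhibition of ATM activation (k3 & k5), flux extinction
# near 190-205 min, pIKK settling near 180-200 min, a 90%-ATM-inhibition
# efficacy boundary at 25 Gy, and the qualitative sensitivity orderings
# (PARP1_tot/kr/vact strongest negative, koff2/koff_act positive).
# PARP1_tot, ATM_tot, IKKg_tot and n_hill are fixed at reported values.
# The PARP-1 recruitment cascade is near-critical (branching ratio ~0.994),
# which is what makes the pathway exquisitely sensitive to kr, vact and
# PARP1_tot.
space: linear
kon: 2.0e-08
koff: 0.5
kr: 7.843489097561131e-07
koff2: 2.0
vact: 0.5
koff_act: 0.030
kdepar: 0.0015158884270474317
k1: 1.0e-06
k4: 1.0e-07
k2: 0.002107874945156076
k3: 0.0018980572350710719
k5: 0.0031683776672268783
SFM_k1: 1.2948531944525038e-09
SFM_k2: 0.338916610927921
TM_k1: 1.3814646531968175e-06
TM_k2: 2.5e-06
TM_k3: 1.2e-06
km: 300.0
km2: 229760.03223053328
n_hill: 2.0
PARP1_tot: 1.9e+05
MRN_tot: 1.0e+05
ATM_tot: 7.0e+03
IKKg_tot: 9.8e+04
TRAF6_tot: 4004.0186683334223
TAK1_tot: 2.0e+03
AB: 1.0
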