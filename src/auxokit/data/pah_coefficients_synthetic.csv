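# SYNTHETIC stand-in coefficient table for predicted adult height (PAH),
# in the functional form of the Khamis-Roche method (Khamis & Roche 1994,
# Pediatrics 94:504-507, and its 1995 erratum): PAH = b0 + b1*stature +
# b2*weight + b3*midparent stature, coefficients tabulated per sex on a
# half-year age grid 4.0-17.5 yr. These are NOT the published values:
# they were constructed 2026-09-28 from standard percent-of-adult-height
# anchors (see docs/methods.md). Units: cm, kg, yr.
sex,age_yr,b0,b1,b2,b3
male,4.0,1.6250,1.293103,0.050000,0.2500
male,4.5,1.6250,1.252332,0.046296,0.2500
male,5.0,1.6250,1.215559,0.042593,0.2500
male,5.5,1.6250,1.182512,0.038889,0.2500
male,6.0,1.6250,1.152074,0.035185,0.2500
male,6.5,1.6250,1.123385,0.031481,0.2500
male,7.0,1.6250,1.096491,0.027778,0.2500
male,7.5,1.6250,1.071237,0.024074,0.2500
male,8.0,1.6250,1.047486,0.020370,0.2500
male,8.5,1.6250,1.025204,0.016667,0.2500
male,9.0,1.6250,1.004016,0.012963,0.2500
male,9.5,1.6250,0.983440,0.009259,0.2500
male,10.0,1.6250,0.964010,0.005556,0.2500
male,10.5,1.6250,0.946372,0.001852,0.2500
male,11.0,1.6250,0.929368,-0.001852,0.2500
male,11.5,1.6250,0.912258,-0.005556,0.2500
male,12.0,1.6250,0.894988,-0.009259,0.2500
male,12.5,1.6250,0.877463,-0.012963,0.2500
male,13.0,1.6250,0.859107,-0.016667,0.2500
male,13.5,1.6250,0.838061,-0.020370,0.2500
male,14.0,1.6250,0.817884,-0.024074,0.2500
male,14.5,1.6250,0.801058,-0.027778,0.2500
male,15.0,1.6250,0.786988,-0.031481,0.2500
male,15.5,1.6250,0.775554,-0.035185,0.2500
male,16.0,1.6250,0.766871,-0.038889,0.2500
male,16.5,1.6250,0.760917,-0.042593,0.2500
male,17.0,1.6250,0.756811,-0.046296,0.2500
male,17.5,1.6250,0.754527,-0.050000,0.2500
female,4.0,-1.6250,1.229508,0.050000,0.2500
female,4.5,-1.6250,1.189998,0.046296,0.2500
female,5.0,-1.6250,1.153846,0.042593,0.2500
female,5.5,-1.6250,1.120657,0.038889,0.2500
female,6.0,-1.6250,1.090116,0.035185,0.2500
female,6.5,-1.6250,1.062140,0.031481,0.2500
female,7.0,-1.6250,1.035912,0.027778,0.2500
female,7.5,-1.6250,1.010695,0.024074,0.2500
female,8.0,-1.6250,0.986842,0.020370,0.2500
female,8.5,-1.6250,0.964705,0.016667,0.2500
female,9.0,-1.6250,0.943396,0.012963,0.2500
female,9.5,-1.6250,0.922420,0.009259,0.2500
female,10.0,-1.6250,0.901442,0.005556,0.2500
female,10.5,-1.6250,0.879718,0.001852,0.2500
female,11.0,-1.6250,0.858124,-0.001852,0.2500
female,11.5,-1.6250,0.836588,-0.005556,0.2500
female,12.0,-1.6250,0.816993,-0.009259,0.2500
female,12.5,-1.6250,0.800509,-0.012963,0.2500
female,13.0,-1.6250,0.786988,-0.016667,0.2500
female,13.5,-1.6250,0.776483,-0.020370,0.2500
female,14.0,-1.6250,0.768443,-0.024074,0.2500
female,14.5,-1.6250,0.762544,-0.027778,0.2500
female,15.0,-1.6250,0.758342,-0.031481,0.2500
female,15.5,-1.6250,0.755552,-0.035185,0.2500
female,16.0,-1.6250,0.753769,-0.038889,0.2500
female,16.5,-1.6250,0.752918,-0.042593,0.2500
female,17.0,-1.6250,0.752257,-0.046296,0.2500
female,17.5,-1.6250,0.751503,-0.050000,0.2500
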