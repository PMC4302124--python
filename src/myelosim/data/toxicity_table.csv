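label,description,context,first_cycle_factor,k_delay_per_h,k_s,k_cg,k_pgb,k_mgb,k_delay_wbc_per_h,k_ly
CHOPo,"Cyclophosphamide 750 mg/m2 d1 + Doxorubicin 50 mg/m2 d1 + Vincristine 2 mg d1","CHOP, age > 60",1.11E+00,6.35E-02,2.16E-01,3.70E-01,2.34E-01,1.69E-04,1.37E-02,1.27E+01
ETo,"Etoposide 100 mg/m2/d d1-3","CHOEP, age > 60",1.10E+00,6.84E-02,2.69E-04,1.97E-02,1.04E+00,3.00E-06,3.50E-02,7.49E-01
CHOPy,"Cyclophosphamide 750 mg/m2 d1 + Doxorubicin 50 mg/m2 d1 + Vincristine 2 mg d1","CHOP, age < 60",1.11E+00,6.35E-02,1.94E-01,3.70E-01,1.06E-01,1.30E-04,1.37E-02,1.08E+01
ETy,"Etoposide 100 mg/m2/d d1-3","BEACOPP, CHOEP, age < 60",1.10E+00,6.84E-02,1.91E-04,5.46E-03,4.02E-01,2.00E-06,3.50E-02,9.30E-02
PROC,"Procarbazine 100 mg/m2/d d1-7","BEACOPP (escalated)",1.09E+00,1.30E-02,2.42E-03,1.03E-02,5.19E-02,7.80E-05,1.00E-05,1.00E-05
CD,"Cyclophosphamide 650 mg/m2 d1 + Doxorubicin 25 mg/m2 d1 + Vincristine 2 mg d1",BEACOPP,1.11E+00,6.35E-02,6.47E-04,3.70E-01,1.48E-02,4.10E-05,1.37E-02,1.08E+01
VB,"Bleomycin 10 mg/m2","BEACOPP (escalated)",1.32E+00,3.33E-03,1.20E-02,3.01E-02,1.57E-02,6.00E-06,,
CDesk,"Cyclophosphamide 1250 mg/m2 d1 + Doxorubicin 35 mg/m2 d1 + Vincristine 2 mg d1","BEACOPP escalated",1.11E+00,6.35E-02,2.12E-01,3.70E-01,2.27E-01,1.84E-04,1.37E-02,1.09E+01
ETesk,"Etoposide 200 mg/m2/d d1-3","BEACOPP escalated",1.10E+00,6.84E-02,1.91E-04,1.18E-02,4.02E-01,3.00E-06,3.50E-02,2.67E+01
CDh,"Cyclophosphamide 1400 mg/m2 d1 + Doxorubicin 32.5 mg/m2/d d1-2 + Vincristine 2 mg d1","high CHOEP",1.11E+00,6.35E-02,1.94E-01,7.26E-01,3.37E-01,1.77E-04,1.37E-02,1.10E+01
ETh,"Etoposide 175 mg/m2/d d1-3","high CHOEP",1.10E+00,6.84E-02,2.42E-02,4.87E-02,6.41E-01,8.00E-06,3.50E-02,7.29E+00
CP,"Carboplatin + Paclitaxel 225 mg/m2","Carboplatin, Paclitaxel",1.00E+00,7.71E-02,5.05E-04,6.00E+01,6.00E+01,2.89E-04,,
TA,"Doxorubicin 60 mg/m2 + Docetaxel 75 mg/m2","Doxorubicin, Docetaxel",2.01E+00,7.24E-02,1.39E-02,2.28E-01,4.22E+00,3.20E-05,,
P225,"Paclitaxel 225 mg/m2, 3-h infusion",ETC,1.05E+00,1.73E-02,2.46E-01,8.21E-01,3.50E+00,7.07E-04,1.97E-01,2.65E-01
P175,"Paclitaxel 175 mg/m2, 3-h infusion",EC-T,1.05E+00,1.73E-02,7.00E-05,8.21E-01,3.50E+00,7.01E-04,1.97E-01,2.65E-01
C600,"Cyclophosphamide 600 mg/m2, 24-h infusion",EC-T,1.01E+00,6.40E-02,1.99E-01,7.43E-01,1.15E-01,1.40E-04,2.50E-02,8.99E+00
C2500,"Cyclophosphamide 2500 mg/m2, 24-h infusion",ETC,1.01E+00,6.40E-02,1.99E-01,7.58E-01,1.27E-01,1.43E-04,2.50E-02,1.31E+01
E90,"Epirubicin 90 mg/m2, 3-h infusion",EC-T,1.99E+00,4.48E-02,1.80E-05,5.51E-02,1.80E-01,5.18E-04,2.42E-02,3.96E+00
E150,"Epirubicin 150 mg/m2, 3-h infusion",ETC,1.99E+00,4.48E-02,2.53E-03,1.56E+00,6.62E+00,1.58E-02,2.42E-02,3.01E+01
Cyta,"Cytarabine 2000 mg/m2",ESHAP,1.00E+00,1.31E-01,4.64E-01,8.80E-03,8.84E-03,2.32E-03,,
Cisp,"Cisplatin 25 mg/m2/d",ESHAP,1.00E+00,6.32E-02,3.24E-02,1.93E-01,9.60E-03,4.10E-04,,
ET40,"Etoposide 40 mg/m2",ESHAP,1.10E+00,6.84E-02,0.00E+00,1.62E-02,8.65E-02,2.00E-06,,
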