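ind00000 ind00000 0 0 0 -9
ind00001 ind00001 0 0 0 -9
ind00002 ind00002 0 0 0 -9
ind00003 ind00003 0 0 0 -9
ind00004 ind00004 0 0 0 -9
ind00005 ind00005 0 0 0 -9
ind00006 ind00006 0 0 0 -9
ind00007 ind00007 0 0 0 -9
ind00008 ind00008 0 0 0 -9
ind00009 ind00009 0 0 0 -9
ind00010 ind00010 0 0 0 -9
ind00011 ind00011 0 0 0 -9
ind00012 ind00012 0 0 0 -9
ind00013 ind00013 0 0 0 -9
ind00014 ind00014 0 0 0 -9
ind00015 ind00015 0 0 0 -9
ind00016 ind00016 0 0 0 -9
ind00017 ind00017 0 0 0 -9
ind00018 ind00018 0 0 0 -9
ind00019 ind00019 0 0 0 -9
ind00020 ind00020 0 0 0 -9
ind00021 ind00021 0 0 0 -9
ind00022 ind00022 0 0 0 -9
ind00023 ind00023 0 0 0 -9
ind00024 ind00024 0 0 0 -9
ind00025 ind00025 0 0 0 -9
ind00026 ind00026 0 0 0 -9
ind00027 ind00027 0 0 0 -9
ind00028 ind00028 0 0 0 -9
ind00029 ind00029 0 0 0 -9
ind00030 ind00030 0 0 0 -9
ind00031 ind00031 0 0 0 -9
ind00032 ind00032 0 0 0 -9
ind00033 ind00033 0 0 0 -9
ind00034 ind00034 0 0 0 -9
ind00035 ind00035 0 0 0 -9
ind00036 ind00036 0 0 0 -9
ind00037 ind00037 0 0 0 -9
ind00038 ind00038 0 0 0 -9
ind00039 ind00039 0 0 0 -9
ind00040 ind00040 0 0 0 -9
ind00041 ind00041 0 0 0 -9
ind00042 ind00042 0 0 0 -9
ind00043 ind00043 0 0 0 -9
ind00044 ind00044 0 0 0 -9
ind00045 ind00045 0 0 0 -9
ind00046 ind00046 0 0 0 -9
ind00047 ind00047 0 0 0 -9
ind00048 ind00048 0 0 0 -9
ind00049 ind00049 0 0 0 -9
ind00050 ind00050 0 0 0 -9
ind00051 ind00051 0 0 0 -9
ind00052 ind00052 0 0 0 -9
ind00053 ind00053 0 0 0 -9
ind00054 ind00054 0 0 0 -9
ind00055 ind00055 0 0 0 -9
ind00056 ind00056 0 0 0 -9
ind00057 ind00057 0 0 0 -9
ind00058 ind00058 0 0 0 -9
ind00059 ind00059 0 0 0 -9
ind00060 ind00060 0 0 0 -9
ind00061 ind00061 0 0 0 -9
ind00062 ind00062 0 0 0 -9
ind00063 ind00063 0 0 0 -9
ind00064 ind00064 0 0 0 -9
ind00065 ind00065 0 0 0 -9
ind00066 ind00066 0 0 0 -9
ind00067 ind00067 0 0 0 -9
ind00068 ind00068 0 0 0 -9
ind00069 ind00069 0 0 0 -9
ind00070 ind00070 0 0 0 -9
ind00071 ind00071 0 0 0 -9
ind00072 ind00072 0 0 0 -9
ind00073 ind00073 0 0 0 -9
ind00074 ind00074 0 0 0 -9
ind00075 ind00075 0 0 0 -9
ind00076 ind00076 0 0 0 -9
ind00077 ind00077 0 0 0 -9
ind00078 ind00078 0 0 0 -9
ind00079 ind00079 0 0 0 -9
ind00080 ind00080 0 0 0 -9
ind00081 ind00081 0 0 0 -9
ind00082 ind00082 0 0 0 -9
ind00083 ind00083 0 0 0 -9
ind00084 ind00084 0 0 0 -9
ind00085 ind00085 0 0 0 -9
ind00086 ind00086 0 0 0 -9
ind00087 ind00087 0 0 0 -9
ind00088 ind00088 0 0 0 -9
ind00089 ind00089 0 0 0 -9
ind00090 ind00090 0 0 0 -9
ind00091 ind00091 0 0 0 -9
ind00092 ind00092 0 0 0 -9
ind00093 ind00093 0 0 0 -9
ind00094 ind00094 0 0 0 -9
ind00095 ind00095 0 0 0 -9
ind00096 ind00096 0 0 0 -9
ind00097 ind00097 0 0 0 -9
ind00098 ind00098 0 0 0 -9
ind00099 ind00099 0 0 0 -9
ind00100 ind00100 0 0 0 -9
ind00101 ind00101 0 0 0 -9
ind00102 ind00102 0 0 0 -9
ind00103 ind00103 0 0 0 -9
ind00104 ind00104 0 0 0 -9
ind00105 ind00105 0 0 0 -9
ind00106 ind00106 0 0 0 -9
ind00107 ind00107 0 0 0 -9
ind00108 ind00108 0 0 0 -9
ind00109 ind00109 0 0 0 -9
ind00110 ind00110 0 0 0 -9
ind00111 ind00111 0 0 0 -9
ind00112 ind00112 0 0 0 -9
ind00113 ind00113 0 0 0 -9
ind00114 ind00114 0 0 0 -9
ind00115 ind00115 0 0 0 -9
ind00116 ind00116 0 0 0 -9
ind00117 ind00117 0 0 0 -9
ind00118 ind00118 0 0 0 -9
ind00119 ind00119 0 0 0 -9
ind00120 ind00120 0 0 0 -9
ind00121 ind00121 0 0 0 -9
ind00122 ind00122 0 0 0 -9
ind00123 ind00123 0 0 0 -9
ind00124 ind00124 0 0 0 -9
ind00125 ind00125 0 0 0 -9
ind00126 ind00126 0 0 0 -9
ind00127 ind00127 0 0 0 -9
ind00128 ind00128 0 0 0 -9
ind00129 ind00129 0 0 0 -9
ind00130 ind00130 0 0 0 -9
ind00131 ind00131 0 0 0 -9
ind00132 ind00132 0 0 0 -9
ind00133 ind00133 0 0 0 -9
ind00134 ind00134 0 0 0 -9
ind00135 ind00135 0 0 0 -9
ind00136 ind00136 0 0 0 -9
ind00137 ind00137 0 0 0 -9
ind00138 ind00138 0 0 0 -9
ind00139 ind00139 0 0 0 -9
ind00140 ind00140 0 0 0 -9
ind00141 ind00141 0 0 0 -9
ind00142 ind00142 0 0 0 -9
ind00143 ind00143 0 0 0 -9
ind00144 ind00144 0 0 0 -9
ind00145 ind00145 0 0 0 -9
ind00146 ind00146 0 0 0 -9
ind00147 ind00147 0 0 0 -9
ind00148 ind00148 0 0 0 -9
ind00149 ind00149 0 0 0 -9
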